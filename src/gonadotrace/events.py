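"""Transient detection and per-cell response metrics.

All inputs are dF/F traces (floor 1.0).  A transient is a local maximum whose
height above the floor exceeds ``theta_amp`` — the "10% of Fmin" criterion,
since dF/F = F/Fmin makes a transient of 10% of Fmin exactly dff - 1 = 0.10 —
with a minimum peak prominence and separation to reject noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .protocol import StimulusProtocol, extended_window, metric_window, response_window

logger = logging.getLogger(__name__)

THETA_AMP = 0.10
MIN_PROMINENCE = 0.05
MIN_SEPARATION = 1.0  # s
THETA_RESP = 0.10
SPONT_EPOCH = 240.0  # s, the 4-min spontaneous-activity epoch


@dataclass(frozen=True)
class EventSet:
    """Detected transients for one cell inside one search window."""

    cell_id: str
    times: np.ndarray  # peak times, s
    amplitudes: np.ndarray  # dff - 1 at the peak
    prominences: np.ndarray
    widths: np.ndarray  # s, at half prominence
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if len(self.times) and (
            self.times[0] < self.window[0] or self.times[-1] >= self.window[1]
        ):
            raise ValueError("event times must lie inside the search window")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class CellMetrics:
    """The per-cell quantities reported for GnRH responses."""

    cell_id: str
    mif: float  # max dF/F in the metric window
    auc: float  # integral of (dF/F - 1) over the metric window, a.u.
    n_oscillations: int
    spontaneous: bool
    responder: bool
    long_lasting: bool = False
    pattern: str | None = None


def detect_transients(
    dff: np.ndarray,
    window: tuple[float, float],
    dt: float,
    theta_amp: float = THETA_AMP,
    min_prominence: float = MIN_PROMINENCE,
    min_separation: float = MIN_SEPARATION,
    cell_id: str = "",
) -> EventSet:
    """Find Ca2+ transients in ``window`` (seconds) of a dF/F trace."""
    dff = np.asarray(dff, dtype=float)
    i0 = max(0, int(np.ceil(window[0] / dt - 1e-9)))
    i1 = min(len(dff), int(np.ceil(window[1] / dt - 1e-9)))
    if i1 - i0 < 3:
        raise ValueError(f"window {window} is empty or too short at dt={dt}")
    seg = dff[i0:i1]
    idx, props = find_peaks(
        seg,
        height=1.0 + theta_amp,
        prominence=min_prominence,
        distance=max(1, int(round(min_separation / dt))),
        width=1,
        rel_height=0.5,
    )
    return EventSet(
        cell_id=cell_id,
        times=(idx + i0) * dt,
        amplitudes=seg[idx] - 1.0,
        prominences=props["prominences"],
        widths=props["widths"] * dt,
        window=(i0 * dt, i1 * dt),
    )


def is_spontaneously_active(
    dff: np.ndarray,
    protocol: StimulusProtocol,
    theta_amp: float = THETA_AMP,
) -> bool:
    """Any transient greater than 10% of Fmin within the 4-min basal epoch?"""
    bl = protocol.baseline
    if bl.duration < SPONT_EPOCH - 1e-9:
        logger.warning(
            "baseline epoch is %.0f s (< the standard %.0f s spontaneous-activity epoch)",
            bl.duration,
            SPONT_EPOCH,
        )
    window = (bl.start, min(bl.end, bl.start + SPONT_EPOCH))
    ev = detect_transients(dff, window, protocol.dt, theta_amp=theta_amp)
    return bool(np.any(ev.amplitudes > theta_amp))


def is_gnrh_responder(
    dff: np.ndarray,
    protocol: StimulusProtocol,
    theta_resp: float = THETA_RESP,
) -> bool:
    """True iff dF/F - 1 reaches ``theta_resp`` between GnRH onset and the
    guarded end of the washout (10 s before the KCl pulse)."""
    t0, t1 = response_window(protocol)
    sl = protocol.slice(t0, t1)
    return bool(np.max(dff[sl]) - 1.0 >= theta_resp)


def count_oscillations(event_set: EventSet) -> int:
    """Number of detected transients (events from the response window;
    long-lasting cells use the window extended to the recording end)."""
    return len(event_set)


def compute_mif(dff: np.ndarray, window: tuple[float, float], dt: float) -> float:
    """Maximal intensity of fluorescence: max dF/F in the window."""
    i0 = max(0, int(np.ceil(window[0] / dt - 1e-9)))
    i1 = min(len(dff), int(np.ceil(window[1] / dt - 1e-9)))
    if i1 <= i0:
        raise ValueError(f"window {window} is empty at dt={dt}")
    return float(np.max(dff[i0:i1]))


def compute_auc(dff: np.ndarray, window: tuple[float, float], dt: float) -> float:
    """Trapezoidal integral of max(dF/F - 1, 0) over the window, a.u."""
    i0 = max(0, int(np.ceil(window[0] / dt - 1e-9)))
    i1 = min(len(dff), int(np.ceil(window[1] / dt - 1e-9)))
    if i1 <= i0:
        raise ValueError(f"window {window} is empty at dt={dt}")
    # include the sample at the right edge so AUC is additive over
    # disjoint windows sharing a boundary
    i1 = min(len(dff), i1 + 1)
    y = np.maximum(np.asarray(dff[i0:i1], dtype=float) - 1.0, 0.0)
    return float(np.trapezoid(y, dx=dt))


def cell_metrics(
    dff: np.ndarray,
    protocol: StimulusProtocol,
    cell_id: str = "",
    long_lasting: bool = False,
    metric_duration: float = 160.0,
    theta_resp: float = THETA_RESP,
) -> CellMetrics:
    """Convenience wrapper computing every per-cell metric at once."""
    win = metric_window(protocol, duration=metric_duration)
    responder = is_gnrh_responder(dff, protocol, theta_resp=theta_resp)
    count_win = extended_window(protocol) if long_lasting else response_window(protocol)
    ev = detect_transients(dff, count_win, protocol.dt, cell_id=cell_id)
    return CellMetrics(
        cell_id=cell_id,
        mif=compute_mif(dff, win, protocol.dt),
        auc=compute_auc(dff, win, protocol.dt),
        n_oscillations=count_oscillations(ev),
        spontaneous=is_spontaneously_active(dff, protocol),
        responder=responder,
        long_lasting=long_lasting,
    )
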