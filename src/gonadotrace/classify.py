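"""Response-pattern classification for GnRH-responsive cells.

Each responder is assigned exactly one of the three Ca2+-mobilization
waveform classes by a deterministic decision tree on the response window:

1. *oscillatory* — at least two detected peaks whose median inter-peak trough
   falls back below half the maximum amplitude (troughs returning toward
   baseline are the defining oscillatory feature, so this rule wins ties);
2. *biphasic* — otherwise, a contiguous stretch of at least
   ``min_plateau_s`` seconds at or above ``plateau_level`` of the maximum
   amplitude, starting at/after the first peak;
3. *transitory* — everything else (a single short, small transient).

Separately, *long-lasting* activity is flagged when detected spikes persist
well beyond the GnRH pulse or reappear repeatedly inside the KCl window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import THETA_RESP, EventSet, detect_transients
from .protocol import StimulusProtocol, extended_window, response_window

PATTERNS = ("oscillatory", "biphasic", "transitory")


class NotAResponderError(ValueError):
    """Raised when a non-responder trace is passed to the classifier."""


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds of the decision tree (all config-exposed)."""

    trough_level: float = 0.5  # oscillatory: median trough < this * max amp
    plateau_level: float = 0.3  # biphasic: dff-1 >= this * max amp ...
    min_plateau_s: float = 30.0  # ... for at least this long, contiguously
    theta_amp: float = 0.10
    min_prominence: float = 0.05
    min_separation: float = 1.0
    late_spike_s: float = 120.0  # long-lasting: spikes this late after GnRH end
    kcl_min_spikes: int = 2  # ... or >= this many spikes in the KCl window


@dataclass(frozen=True)
class PatternLabel:
    pattern: str
    long_lasting: bool
    n_peaks: int
    plateau_time: float  # s above plateau_level * max amp, contiguous
    trough_ratio: float  # median trough / max amplitude (nan if < 2 peaks)
    max_amplitude: float


def _features(dff, protocol, params):
    t0, t1 = response_window(protocol)
    dt = protocol.dt
    ev = detect_transients(
        dff,
        (t0, t1),
        dt,
        theta_amp=params.theta_amp,
        min_prominence=params.min_prominence,
        min_separation=params.min_separation,
    )
    sl = protocol.slice(t0, t1)
    seg = np.asarray(dff[sl], dtype=float) - 1.0
    max_amp = float(seg.max())
    peak_idx = np.round(ev.times / dt).astype(int) - sl.start

    trough_ratio = np.nan
    if len(ev) >= 2:
        troughs = [seg[a:b + 1].min() for a, b in zip(peak_idx[:-1], peak_idx[1:])]
        trough_ratio = float(np.median(troughs) / max_amp) if max_amp > 0 else np.nan

    start = int(peak_idx[0]) if len(ev) else int(np.argmax(seg))
    above = seg[start:] >= params.plateau_level * max_amp
    # longest contiguous run from/after the first peak
    best = run = 0
    for a in above:
        run = run + 1 if a else 0
        best = max(best, run)
    plateau_time = best * dt
    return ev, len(ev), plateau_time, trough_ratio, max_amp


def classify_pattern(
    dff: np.ndarray,
    protocol: StimulusProtocol,
    params: ClassifyParams = ClassifyParams(),
) -> PatternLabel:
    """Assign one Ca2+-mobilization pattern to a GnRH responder."""
    ev, n_peaks, plateau_time, trough_ratio, max_amp = _features(dff, protocol, params)
    if max_amp < THETA_RESP:
        raise NotAResponderError(
            f"trace max amplitude {max_amp:.3f} below the responder threshold; "
            "classify_pattern is defined for GnRH responders only"
        )
    if n_peaks >= 2 and trough_ratio < params.trough_level:
        pattern = "oscillatory"
    elif plateau_time >= params.min_plateau_s:
        pattern = "biphasic"
    else:
        pattern = "transitory"
    ll = flag_long_lasting(dff, protocol, params=params)
    if pattern == "transitory":
        ll = False
    return PatternLabel(
        pattern=pattern,
        long_lasting=ll,
        n_peaks=n_peaks,
        plateau_time=plateau_time,
        trough_ratio=trough_ratio,
        max_amplitude=max_amp,
    )


def flag_long_lasting(
    dff: np.ndarray,
    protocol: StimulusProtocol,
    event_set: EventSet | None = None,
    params: ClassifyParams = ClassifyParams(),
) -> bool:
    """Oscillatory activity persisting into washout/KCl.

    True iff a spike is detected later than ``late_spike_s`` after GnRH
    offset, or at least ``kcl_min_spikes`` spikes fall inside the KCl window
    (the depolarization response itself contributes a single peak, so the
    default of 2 requires genuine ongoing activity).
    """
    if event_set is None:
        event_set = detect_transients(
            dff,
            extended_window(protocol),
            protocol.dt,
            theta_amp=params.theta_amp,
            min_prominence=params.min_prominence,
            min_separation=params.min_separation,
        )
    t = event_set.times
    # the expected single depolarization peak lives in the KCl epoch, so the
    # late-spike rule only looks at the washout before it
    late = np.any((t > protocol.gnrh.end + params.late_spike_s) & (t < protocol.kcl.start))
    in_kcl = np.sum((t >= protocol.kcl.start) & (t < protocol.kcl.end))
    return bool(late or in_kcl >= params.kcl_min_spikes)
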