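"""Raw trace loading, photobleach detrending, dF/F normalization, viability gate.

Normalization follows dF/F = F / Fmin: each trace is divided by its minimum
fluorescence, so the normalized floor is exactly 1.0 and transient amplitudes
are expressed as fractions of Fmin.  Fmin is taken after slope correction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter

from .protocol import StimulusProtocol
from .synth import RawRecording

logger = logging.getLogger(__name__)

DT_TOLERANCE = 1e-6  # s, allowed jitter in the sampling interval


class TraceLoadError(ValueError):
    pass


class EmptyRecordingError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizedRecording:
    """Viability-gated, detrended, dF/F-normalized traces."""

    protocol: StimulusProtocol
    dff: np.ndarray  # (n_frames, n_retained)
    roi_ids: tuple[str, ...]
    fmin: np.ndarray  # per retained ROI, fluorescence units

    def __post_init__(self) -> None:
        if self.dff.shape[1] != len(self.roi_ids) or self.fmin.shape[0] != len(self.roi_ids):
            raise ValueError("dff/fmin columns must match roi_ids")
        if np.any(self.fmin <= 0):
            raise ValueError("fmin must be positive")

    @property
    def n_cells(self) -> int:
        return self.dff.shape[1]


def read_trace_matrix(
    path: str | Path,
    protocol: StimulusProtocol | None = None,
    time_unit: str = "s",
) -> RawRecording:
    """Load a trace-matrix CSV (first column time, remaining columns ROIs).

    Validates a uniform sampling interval, strictly positive fluorescence and
    absence of missing values; ``time_unit='ms'`` converts the time column to
    seconds.  When ``protocol`` is omitted a ``<stem>.json`` sidecar written
    by :func:`gonadotrace.synth.write_recording` is read instead.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise TraceLoadError(f"{path}: need a time column plus at least one ROI")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if time_unit == "ms":
        t = t / 1000.0
    elif time_unit != "s":
        raise TraceLoadError(f"unsupported time unit {time_unit!r}")
    F = df.iloc[:, 1:].to_numpy(dtype=float)

    if np.isnan(F).any():
        row = int(np.where(np.isnan(F).any(axis=1))[0][0])
        raise TraceLoadError(f"{path}: missing fluorescence value at row {row}")
    if (F <= 0).any():
        row = int(np.where((F <= 0).any(axis=1))[0][0])
        raise TraceLoadError(f"{path}: non-positive fluorescence at row {row}")
    dts = np.diff(t)
    if len(dts) == 0 or np.any(dts <= 0):
        raise TraceLoadError(f"{path}: time column must be strictly increasing")
    dt = float(dts[0])
    bad = np.where(np.abs(dts - dt) > DT_TOLERANCE)[0]
    if bad.size:
        raise TraceLoadError(f"{path}: non-uniform sampling at row {int(bad[0]) + 1}")

    if protocol is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise TraceLoadError(
                f"{path}: no protocol given and sidecar {sidecar.name} not found"
            )
        with open(sidecar) as fh:
            protocol = StimulusProtocol.from_dict(json.load(fh)["protocol"])
    if abs(protocol.dt - dt) > DT_TOLERANCE or protocol.n_frames != len(t):
        raise TraceLoadError(
            f"{path}: data geometry (dt={dt}, n={len(t)}) does not match protocol "
            f"(dt={protocol.dt}, n={protocol.n_frames})"
        )
    return RawRecording(
        protocol=protocol,
        animal_id=path.stem,
        F=F,
        roi_ids=tuple(str(c) for c in df.columns[1:]),
    )


def _baseline_percentile(trace: np.ndarray, dt: float, percentile: float, window_s: float) -> np.ndarray:
    size = max(3, int(round(window_s / dt)))
    return percentile_filter(trace, percentile, size=size, mode="nearest")


def detrend_bleach(
    trace: np.ndarray,
    protocol: StimulusProtocol,
    percentile: float = 10.0,
    window_s: float = 20.0,
) -> np.ndarray:
    """Correct the multiplicative photobleaching slope of one trace.

    A running lower-percentile baseline is computed over the pre-stimulus
    epoch (stimulus windows and their aftermath are excluded so evoked
    activity cannot bias the fit), a single exponential ``a * exp(-b t)`` is
    fitted to it, and the trace is divided by the fitted curve and rescaled
    to the fit's initial value ``a`` — i.e. multiplied by ``exp(b t)``.
    Falls back to a linear fit (with a logged warning) if the exponential
    fit is unusable.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("detrend_bleach expects a single trace")
    if len(trace) < 100:
        raise ValueError("trace too short to detrend (< 100 frames)")
    dt = protocol.dt
    t = np.arange(len(trace)) * dt

    stop = protocol.frame(min(protocol.gnrh.start, protocol.baseline.end))
    stop = max(stop, min(len(trace), 100))
    base = _baseline_percentile(trace[:stop], dt, percentile, window_s)
    tb = t[:stop]

    if np.all(base > 0):
        # pass 1: coarse decay rate from the running-percentile curve
        slope0, _ = np.polyfit(tb, np.log(base), 1)
        # pass 2: flatten, then refit on quiet frames only (within 0.2% of
        # the stationary floor) so transient tails cannot tilt the fit
        flat = trace[:stop] * np.exp(-slope0 * tb)
        floor = np.percentile(flat, percentile)
        quiet = flat <= floor * 1.002
        if quiet.sum() < 20:
            quiet = np.ones(stop, dtype=bool)
        slope, _ = np.polyfit(tb[quiet], np.log(trace[:stop][quiet]), 1)
        b = -slope
        # output = trace / (a e^{-bt}) * a = trace * e^{bt}
        return trace * np.exp(b * t)

    logger.warning("non-positive baseline percentile; falling back to linear detrend")
    c, a = np.polyfit(tb, base, 1)
    fit = a + c * t
    if np.any(fit <= 0) or a <= 0:
        logger.warning("linear detrend degenerate; returning trace unchanged")
        return trace.copy()
    return trace / fit * a


def normalize_dff(trace: np.ndarray) -> np.ndarray:
    """dF/F = F / Fmin.  The minimum of the output is exactly 1.0."""
    trace = np.asarray(trace, dtype=float)
    fmin = trace.min()
    if fmin <= 0:
        raise ValueError(f"cannot normalize: minimum fluorescence {fmin} <= 0")
    return trace / fmin


def viability_filter(
    recording: RawRecording,
    protocol: StimulusProtocol | None = None,
    theta_kcl: float = 0.10,
    gate: bool = True,
    detrend: bool = True,
) -> NormalizedRecording:
    """Detrend, normalize, and retain ROIs that respond to the KCl pulse.

    A cell is viable if its detrended dF/F exceeds ``1 + theta_kcl`` inside
    the KCl window; the retained set defines the 100% denominator for all
    population fractions.  ``gate=False`` retains every ROI (needed for
    extracellular-Ca2+-free paradigms, where even viable cells cannot
    respond to depolarization).
    """
    proto = protocol if protocol is not None else recording.protocol
    if gate and proto.kcl is None:
        raise ValueError("protocol has no KCl epoch; disable the gate explicitly")
    sl = proto.slice(proto.kcl.start, proto.kcl.end)

    keep_dff, keep_ids, keep_fmin = [], [], []
    for j, roi in enumerate(recording.roi_ids):
        trace = recording.F[:, j]
        if detrend:
            trace = detrend_bleach(trace, proto)
        fmin = trace.min()
        if fmin <= 0:
            continue
        dff = trace / fmin
        if gate and not (dff[sl].max() > 1.0 + theta_kcl):
            continue
        keep_dff.append(dff)
        keep_ids.append(roi)
        keep_fmin.append(fmin)

    if not keep_ids:
        raise EmptyRecordingError(
            f"{recording.animal_id}: no ROI passed the KCl viability gate"
        )
    return NormalizedRecording(
        protocol=proto,
        dff=np.column_stack(keep_dff),
        roi_ids=tuple(keep_ids),
        fmin=np.array(keep_fmin),
    )


def write_normalized(rec: NormalizedRecording, outdir: str | Path, animal_id: str) -> Path:
    """Write normalized traces plus a JSON sidecar of fmin / retained ROIs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rec.dff, columns=list(rec.roi_ids))
    df.insert(0, "time_s", rec.protocol.times())
    path = outdir / f"{animal_id}_dff.csv"
    df.to_csv(path, index=False, float_format="%.6f")
    with open(outdir / f"{animal_id}_dff.json", "w") as fh:
        json.dump(
            {
                "animal_id": animal_id,
                "protocol": rec.protocol.to_dict(),
                "roi_ids": list(rec.roi_ids),
                "fmin": rec.fmin.tolist(),
            },
            fh,
            indent=1,
        )
    return path
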