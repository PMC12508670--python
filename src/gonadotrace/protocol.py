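"""Stimulus protocols for perifusion calcium-imaging recordings.

A recording is a uniformly sampled fluorescence time series partitioned into
ordered epochs: a pre-stimulus *baseline* used to score spontaneous activity,
a short GnRH pulse, a washout, and a terminal depolarizing high-potassium
(KCl) pulse used as the cell-viability gate.  Optional intervention windows
(nifedipine, extracellular-Ca2+-free) may overlay the washout/KCl phase.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

#: default sampling interval, seconds per frame
DEFAULT_DT = 0.2
#: default recording length, frames (480 s at 0.2 s/frame)
DEFAULT_N_FRAMES = 2400

GNRH_DURATION = 30.0
KCL_DURATION = 30.0
BASELINE_DURATION = 240.0  # the 4-min spontaneous-activity epoch
_TAIL = 10.0  # quiet seconds after the KCl pulse
_MIN_BASELINE = 20.0
_MIN_WASHOUT = 20.0

INTERVENTION_KINDS = ("nifedipine", "ca_free")


class ProtocolError(ValueError):
    """Raised when epochs are inconsistent with the recording geometry."""


@dataclass(frozen=True)
class Epoch:
    """Half-open time interval [start, end) in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ProtocolError(f"epoch end must exceed start, got [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end

    def overlaps(self, other: "Epoch") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class StimulusProtocol:
    """Epoch boundaries and stimulus identities on a shared time base."""

    dt: float = DEFAULT_DT
    n_frames: int = DEFAULT_N_FRAMES
    baseline: Epoch = field(default_factory=lambda: Epoch(0.0, 240.0))
    gnrh: Epoch = field(default_factory=lambda: Epoch(240.0, 270.0))
    washout: Epoch = field(default_factory=lambda: Epoch(270.0, 440.0))
    kcl: Epoch = field(default_factory=lambda: Epoch(440.0, 470.0))
    interventions: tuple[tuple[str, Epoch], ...] = ()

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ProtocolError("dt must be positive")
        if self.n_frames < 2:
            raise ProtocolError("n_frames must be at least 2")
        named = [
            ("baseline", self.baseline),
            ("gnrh", self.gnrh),
            ("washout", self.washout),
            ("kcl", self.kcl),
        ]
        total = self.total_time
        for name, ep in named:
            if ep.start < 0 or ep.end > total + 1e-9:
                raise ProtocolError(f"epoch {name} [{ep.start}, {ep.end}) outside recording [0, {total})")
        for (na, a), (nb, b) in zip(named, named[1:]):
            if a.overlaps(b):
                raise ProtocolError(f"epochs {na} and {nb} overlap")
            if b.start < a.end:
                raise ProtocolError(f"epochs {na} and {nb} out of order")
        for kind, ep in self.interventions:
            if kind not in INTERVENTION_KINDS:
                raise ProtocolError(f"unknown intervention {kind!r}; valid kinds: {INTERVENTION_KINDS}")
            if ep.start < 0 or ep.end > total + 1e-9:
                raise ProtocolError(f"intervention {kind} window outside recording")

    @property
    def total_time(self) -> float:
        return self.dt * self.n_frames

    def times(self):
        import numpy as np

        return np.arange(self.n_frames) * self.dt

    def frame(self, t: float) -> int:
        """Index of the first frame at or after time t (clipped to range)."""
        import math

        return min(max(int(math.ceil(t / self.dt - 1e-9)), 0), self.n_frames)

    def slice(self, start: float, end: float) -> slice:
        return slice(self.frame(start), self.frame(end))

    def with_intervention(self, kind: str, window: Epoch) -> "StimulusProtocol":
        return replace(self, interventions=self.interventions + ((kind, window),))

    def to_dict(self) -> dict:
        d = {
            "dt": self.dt,
            "n_frames": self.n_frames,
            "baseline": [self.baseline.start, self.baseline.end],
            "gnrh": [self.gnrh.start, self.gnrh.end],
            "washout": [self.washout.start, self.washout.end],
            "kcl": [self.kcl.start, self.kcl.end],
            "interventions": [[k, [e.start, e.end]] for k, e in self.interventions],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            dt=d["dt"],
            n_frames=d["n_frames"],
            baseline=Epoch(*d["baseline"]),
            gnrh=Epoch(*d["gnrh"]),
            washout=Epoch(*d["washout"]),
            kcl=Epoch(*d["kcl"]),
            interventions=tuple((k, Epoch(*w)) for k, w in d.get("interventions", [])),
        )


def make_protocol(**config) -> StimulusProtocol:
    """Build a stimulus protocol, filling in the default perifusion design.

    With no arguments this returns the standard 480 s protocol: a 240 s
    baseline, GnRH at [240, 270), washout, and KCl at [440, 470), sampled at
    0.2 s per frame.  Epochs may be overridden individually (``baseline=``,
    ``gnrh=`` ... as (start, end) pairs) or the recording geometry changed
    via ``dt`` / ``n_frames``; when the default epochs no longer fit, the
    baseline (and if necessary the washout) is truncated with a warning.
    """
    dt = float(config.pop("dt", DEFAULT_DT))
    n_frames = int(config.pop("n_frames", DEFAULT_N_FRAMES))
    total = dt * n_frames

    explicit = {k: config.pop(k) for k in ("baseline", "gnrh", "washout", "kcl") if k in config}
    interventions = tuple(
        (k, w if isinstance(w, Epoch) else Epoch(*w)) for k, w in config.pop("interventions", ())
    )
    gnrh_dur = float(config.pop("gnrh_duration", GNRH_DURATION))
    kcl_dur = float(config.pop("kcl_duration", KCL_DURATION))
    if config:
        raise TypeError(f"unknown protocol options: {sorted(config)}")
    if gnrh_dur <= 0 or kcl_dur <= 0:
        raise ProtocolError("stimulus durations must be positive")

    def as_epoch(v):
        return v if isinstance(v, Epoch) else Epoch(*v)

    if len(explicit) == 4:
        return StimulusProtocol(
            dt=dt, n_frames=n_frames, interventions=interventions,
            **{k: as_epoch(v) for k, v in explicit.items()},
        )

    # lay out defaults back-to-front so the stimuli keep their durations
    baseline_dur = BASELINE_DURATION
    budget = total - _TAIL - kcl_dur - gnrh_dur
    washout_dur = min(170.0, max(_MIN_WASHOUT, budget - baseline_dur))
    if baseline_dur + washout_dur > budget:
        baseline_dur = budget - washout_dur
        if baseline_dur < _MIN_BASELINE:
            raise ProtocolError(
                f"recording of {total:.0f} s too short for the default stimulus sequence"
            )
        msg = (
            f"recording is {total:.0f} s: baseline truncated to {baseline_dur:.0f} s "
            f"(< the standard {BASELINE_DURATION:.0f} s spontaneous-activity epoch)"
        )
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)

    t0 = baseline_dur
    defaults = {
        "baseline": Epoch(0.0, t0),
        "gnrh": Epoch(t0, t0 + gnrh_dur),
        "washout": Epoch(t0 + gnrh_dur, t0 + gnrh_dur + washout_dur),
        "kcl": Epoch(t0 + gnrh_dur + washout_dur, t0 + gnrh_dur + washout_dur + kcl_dur),
    }
    for k, v in explicit.items():
        defaults[k] = as_epoch(v)
    return StimulusProtocol(dt=dt, n_frames=n_frames, interventions=interventions, **defaults)


def response_window(protocol: StimulusProtocol, guard: float = 10.0) -> tuple[float, float]:
    """GnRH response window: stimulus onset to ``guard`` s before the KCl pulse.

    The guard keeps the depolarization response out of GnRH metrics.
    """
    return (protocol.gnrh.start, protocol.kcl.start - guard)


def metric_window(protocol: StimulusProtocol, duration: float = 160.0, guard: float = 10.0) -> tuple[float, float]:
    """Window over which MIF and AUC are computed (default 160 s post-onset)."""
    t0, t1 = response_window(protocol, guard=guard)
    return (t0, min(t0 + duration, t1))


def extended_window(protocol: StimulusProtocol) -> tuple[float, float]:
    """Response window extended to the recording end (long-lasting cells)."""
    return (protocol.gnrh.start, protocol.total_time)
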