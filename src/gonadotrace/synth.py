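"""Synthetic perifusion recordings with known ground truth.

Each cell's fluorescence trace is built as

    F(t) = F0 * exp(-bleach_rate * t) * (1 + r(t)) + eps(t)

where ``r(t)`` is a sum of positive transient kernels (spontaneous events in
the baseline epoch, the GnRH-evoked response, the terminal KCl depolarization
response) and ``eps`` is white Gaussian noise with SD ``noise_sd * F0``.
Transient kernels are double exponentials (fast rise, slower decay),
renormalized on the sampling grid so the drawn amplitude is attained exactly
at a sampled frame.

The GnRH response takes one of three shapes, mirroring the waveform classes
seen in gonadotrophs:

* *oscillatory* — a train of ``n_spikes_true`` kernels with jittered
  (gamma-like) inter-spike intervals; the leading spike carries the cell's
  peak amplitude.  Long-lasting cells spread the train to the recording end,
  through washout and the KCl pulse.
* *biphasic* — an initial peak blending into a sustained plateau that decays
  slowly after ``plateau_dur`` seconds.
* *transitory* — a single small kernel.

Ground-truth labels and event counts are returned alongside the raw matrix so
the downstream pipeline can be validated by round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .params import GROUPS, PATTERNS, GroupParams, default_group_params
from .protocol import Epoch, StimulusProtocol, make_protocol

# kernel time constants, seconds
TAU_RISE = 0.5
TAU_DECAY = 3.0
TAU_PLATEAU_ON = 3.0
TAU_PLATEAU_OFF = 10.0
KCL_TAU_DECAY = 6.0
#: floor on individual spike amplitudes so every true event is detectable
SPIKE_AMP_FLOOR = 0.12
#: floor on the peak response amplitude of a responder
RESPONSE_AMP_FLOOR = 0.11
MIN_ISI = 1.5  # s, keeps consecutive spikes resolvable at 0.2 s sampling

# per-cell substream ids (counter-based seeding: cell i is reproducible
# independently of n_cells)
_S_LABELS, _S_EVENTS, _S_NOISE, _S_INTERVENTION = 0, 1, 2, 3


@dataclass(frozen=True)
class RawRecording:
    """Raw fluorescence matrix: one row per frame, one column per ROI."""

    protocol: StimulusProtocol
    animal_id: str
    F: np.ndarray
    roi_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.F.ndim != 2 or self.F.shape[0] != self.protocol.n_frames:
            raise ValueError("F must be (n_frames, n_rois)")
        if np.any(self.F <= 0):
            raise ValueError("fluorescence must be strictly positive")


@dataclass
class GroundTruth:
    """Per-cell generator labels, aligned with the ROI columns."""

    cell_ids: list[str]
    viable: np.ndarray
    is_gonadotroph: np.ndarray
    pattern: list[str | None]
    n_spikes_true: np.ndarray
    long_lasting: np.ndarray
    spont_event_times: list[np.ndarray]

    def __post_init__(self) -> None:
        for i, p in enumerate(self.pattern):
            if (p is not None) != bool(self.is_gonadotroph[i]):
                raise ValueError("pattern must be defined iff the cell is a gonadotroph")
            if p == "oscillatory" and self.n_spikes_true[i] < 1:
                raise ValueError("oscillatory cells need n_spikes_true >= 1")

    def __len__(self) -> int:
        return len(self.cell_ids)

    @property
    def spontaneous(self) -> np.ndarray:
        return np.array([len(t) > 0 for t in self.spont_event_times])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "viable": self.viable,
                "is_gonadotroph": self.is_gonadotroph,
                "pattern": self.pattern,
                "n_spikes_true": self.n_spikes_true,
                "long_lasting": self.long_lasting,
                "spontaneous": self.spontaneous,
                "n_spont_events": [len(t) for t in self.spont_event_times],
            }
        )


@dataclass
class CellEvents:
    """Resolved event program for one cell, before waveform rendering."""

    spont: list[tuple[float, float]] = field(default_factory=list)  # (time, amp)
    pattern: str | None = None
    peak_amp: float = 0.0  # A; MIF of the noiseless trace is 1 + A
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    spike_amps: np.ndarray = field(default_factory=lambda: np.empty(0))
    plateau_onset: float | None = None  # biphasic only
    kcl_time: float | None = None
    kcl_amp: float = 0.0


@dataclass(frozen=True)
class RecordingSpec:
    """Everything needed to (re)generate one recording deterministically."""

    group: str
    n_cells: int
    seed: int | Sequence[int]
    protocol: StimulusProtocol | None = None
    params: GroupParams | None = None
    animal_id: str | None = None

    def resolve(self) -> tuple[StimulusProtocol, GroupParams, str]:
        proto = self.protocol if self.protocol is not None else make_protocol()
        params = self.params if self.params is not None else default_group_params(self.group)
        animal = self.animal_id if self.animal_id is not None else f"{self.group}-s{self.seed}"
        return proto, params, animal


def _cell_rng(seed, cell_index: int, stream: int) -> np.random.Generator:
    key = list(np.atleast_1d(np.asarray(seed, dtype=np.int64))) + [cell_index, stream]
    return np.random.default_rng([int(k) for k in key])


def _kernel(times: np.ndarray, onset: float, amp: float, tau_r: float, tau_d: float) -> np.ndarray:
    """Double-exponential transient, renormalized to its sampled maximum."""
    u = times - onset
    out = np.zeros_like(times)
    m = u >= 0
    if not m.any():
        return out
    s = np.exp(-u[m] / tau_d) - np.exp(-u[m] / tau_r)
    peak = s.max()
    if peak > 0:
        out[m] = amp * s / peak
    return out


def _plateau_kernel(times: np.ndarray, onset: float, dur: float) -> np.ndarray:
    """Slow-rising plateau held for ``dur`` seconds, then exponential decay."""
    u = times - onset
    out = np.zeros_like(times)
    m = u >= 0
    um = u[m]
    rise = 1.0 - np.exp(-um / TAU_PLATEAU_ON)
    decay = np.where(um > dur, np.exp(-(um - dur) / TAU_PLATEAU_OFF), 1.0)
    out[m] = rise * decay
    peak = out.max()
    if peak > 0:
        out /= peak
    return out


def _draw_spike_count(params: GroupParams, rng: np.random.Generator) -> int:
    """Spike count for an oscillatory responder, truncated at >= 2.

    Negative binomial matched to the group mean/SD; when the printed SD is
    below the mean (no NB exists), a rounded clipped normal is used.
    """
    m, sd = params.spike_count_mean, params.spike_count_sd
    var = sd * sd
    for _ in range(200):
        if var > m:
            r = m * m / (var - m)
            p = r / (r + m)
            n = int(rng.negative_binomial(r, p))
        else:
            n = int(round(rng.normal(m, sd)))
        if n >= 2:
            return n
    return 2


def _spike_train(
    rng: np.random.Generator, onset: float, duration: float, n: int
) -> np.ndarray:
    """n spike times in [onset, onset + duration] with gamma-jittered ISIs.

    The leading spike sits at the onset; intervals are drawn from a gamma
    distribution, then affinely rescaled to fill the duration while keeping
    every interval above a resolvability floor.
    """
    if n <= 1:
        return np.array([onset])
    # the floor scales with the mean interval so troughs between consecutive
    # kernels always fall deep enough for the detector's prominence criterion
    min_isi = max(MIN_ISI, 0.5 * duration / (n - 1))
    if (n - 1) * min_isi > duration:
        min_isi = 0.9 * duration / (n - 1)
    g = rng.gamma(2.0, 1.0, size=n - 1)
    isi = min_isi + g * (duration - (n - 1) * min_isi) / g.sum()
    return onset + np.concatenate([[0.0], np.cumsum(isi)])


def draw_ground_truth(
    params: GroupParams, n_cells: int, seed, protocol: StimulusProtocol | None = None
) -> tuple[GroundTruth, list[CellEvents]]:
    """Draw per-cell labels and event programs (no waveform rendering).

    Uses one independent, counter-derived random substream per cell, so cell
    ``i`` is identical whatever ``n_cells`` is.
    """
    proto = protocol if protocol is not None else make_protocol()
    cell_ids, viable, gonado, pattern = [], [], [], []
    n_spikes, long_last, spont_times, programs = [], [], [], []

    bl = proto.baseline
    # spontaneous events stop 15 s before the GnRH pulse so their tails do
    # not leak into the response window
    spont_lo, spont_hi = bl.start + 2.0, min(bl.end, proto.gnrh.start) - 15.0
    resp_t1 = proto.kcl.start - 10.0

    for i in range(n_cells):
        rng = _cell_rng(seed, i, _S_LABELS)
        ev_rng = _cell_rng(seed, i, _S_EVENTS)
        ev = CellEvents()
        cell_ids.append(f"roi{i:04d}")

        is_viable = rng.random() >= params.frac_nonviable
        viable.append(is_viable)
        if not is_viable:
            gonado.append(False)
            pattern.append(None)
            n_spikes.append(0)
            long_last.append(False)
            spont_times.append(np.empty(0))
            programs.append(ev)
            continue

        ev.kcl_time = proto.kcl.start + ev_rng.uniform(0.2, 1.0)
        ev.kcl_amp = ev_rng.uniform(0.4, 0.8)

        # spontaneous baseline transients (all viable cells)
        if rng.random() < params.frac_spontaneous and spont_hi > spont_lo:
            lam = params.spont_rate * (spont_hi - spont_lo) / 60.0
            k = ev_rng.poisson(lam)
            ts = np.sort(ev_rng.uniform(spont_lo, spont_hi, size=k))
            keep = []
            for t in ts:  # enforce 8 s separation so events stay distinct
                if not keep or t - keep[-1] >= 8.0:
                    keep.append(t)
            ev.spont = [(t, ev_rng.uniform(0.12, 0.25)) for t in keep]
        spont_times.append(np.array([t for t, _ in ev.spont]))

        is_g = rng.random() < params.frac_responder
        gonado.append(is_g)
        if not is_g:
            pattern.append(None)
            n_spikes.append(0)
            long_last.append(False)
            programs.append(ev)
            continue

        pat = PATTERNS[rng.choice(3, p=np.asarray(params.pattern_mix))]
        pattern.append(pat)
        ev.pattern = pat
        onset = proto.gnrh.start + ev_rng.uniform(1.0, 3.0)

        if pat == "transitory":
            ev.peak_amp = ev_rng.uniform(0.12, 0.18)
            ev.spike_times = np.array([onset])
            ev.spike_amps = np.array([ev.peak_amp])
            n_spikes.append(1)
            long_last.append(False)
        else:
            amp = max(
                RESPONSE_AMP_FLOOR,
                ev_rng.normal(params.mif_mean - 1.0 - params.amp_cal, params.mif_sd),
            )
            ev.peak_amp = amp
            if pat == "biphasic":
                ev.spike_times = np.array([onset])
                ev.spike_amps = np.array([amp])
                ev.plateau_onset = onset
                n_spikes.append(1)
                long_last.append(False)
            else:  # oscillatory
                n = _draw_spike_count(params, ev_rng)
                ll = rng.random() < params.frac_long_lasting
                if ll:
                    dur = proto.total_time - 5.0 - onset
                else:
                    # canonical trains stretch with the spike count but stop
                    # 15 s clear of the long-lasting late-spike rule (120 s
                    # past GnRH offset) and of the KCl guard
                    dur_max = min(proto.gnrh.end + 105.0, resp_t1 - 2.0) - onset
                    dur = min(dur_max, max(params.osc_duration, (n - 1) * 2.4))
                # capacity limit: spikes denser than the detector can resolve
                # are not generated (the drawn count is clipped)
                n = min(n, 1 + int(0.9 * dur / MIN_ISI))
                ts = _spike_train(ev_rng, onset, dur, n)
                if ll:
                    # long-lasting activity persists through the KCl pulse;
                    # guarantee a spike there so the viability gate holds
                    in_kcl = (ts >= proto.kcl.start + 1.0) & (ts < proto.kcl.end - 1.0)
                    if not in_kcl.any():
                        ts = ts.copy()
                        ts[np.argmin(np.abs(ts - (proto.kcl.start + 10.0)))] = proto.kcl.start + 10.0
                        ts.sort()
                lo, hi = params.osc_amp_range
                amps = np.maximum(SPIKE_AMP_FLOOR, amp * ev_rng.uniform(lo, hi, size=n))
                amps[0] = amp
                ev.spike_times, ev.spike_amps = ts, amps
                if ll:
                    # in long-lasting cells the depolarization window shows
                    # ongoing oscillations instead of a discrete KCl peak
                    ev.kcl_amp = 0.0
                    ev.kcl_time = None
                n_spikes.append(n)
                long_last.append(ll)
        programs.append(ev)

    truth = GroundTruth(
        cell_ids=cell_ids,
        viable=np.array(viable),
        is_gonadotroph=np.array(gonado),
        pattern=pattern,
        n_spikes_true=np.array(n_spikes),
        long_lasting=np.array(long_last),
        spont_event_times=spont_times,
    )
    return truth, programs


def render_cell(
    ev: CellEvents,
    params: GroupParams,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
    f0: float = 100.0,
) -> np.ndarray:
    """Render one cell's fluorescence trace from its event program."""
    t = protocol.times()
    r = np.zeros_like(t)
    for t0, a in ev.spont:
        r += _kernel(t, t0, a, TAU_RISE, TAU_DECAY)

    if ev.pattern == "biphasic":
        p = params.plateau_frac
        shape = (1.0 - p) * _kernel(t, ev.spike_times[0], 1.0, TAU_RISE, TAU_DECAY)
        shape += p * _plateau_kernel(t, ev.plateau_onset, params.plateau_dur)
        peak = shape.max()
        if peak > 0:
            r += ev.peak_amp * shape / peak
    elif len(ev.spike_times):
        # adapt kernel width to the train density so spikes stay resolved
        if len(ev.spike_times) > 1:
            mean_isi = float(np.mean(np.diff(ev.spike_times)))
        else:
            mean_isi = np.inf
        tau_d = min(TAU_DECAY, 0.35 * mean_isi)
        tau_r = min(TAU_RISE, tau_d / 3.0)
        for t0, a in zip(ev.spike_times, ev.spike_amps):
            r += _kernel(t, t0, a, tau_r, tau_d)

    if ev.kcl_time is not None and ev.kcl_amp > 0:
        r += _kernel(t, ev.kcl_time, ev.kcl_amp, TAU_RISE, KCL_TAU_DECAY)

    F = f0 * np.exp(-params.bleach_rate * t) * (1.0 + r)
    if params.noise_sd > 0:
        F = F + rng.normal(0.0, params.noise_sd * f0, size=t.shape)
    return np.maximum(F, 1e-6)


def synth_cell(
    params: GroupParams,
    ev: CellEvents,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
    f0: float = 100.0,
) -> np.ndarray:
    """Render a fluorescence sequence for a pre-built cell event program."""
    return render_cell(ev, params, protocol, rng, f0=f0)


def _apply_transform(
    programs: list[CellEvents],
    truth: GroundTruth,
    kind: str,
    window: Epoch,
    params: GroupParams,
    seed,
    protocol: StimulusProtocol,
    nif_amp_factor: float = 0.4,
    nif_rate_factor: float = 0.3,
    nif_ll_amp_factor: float = 0.75,
    nif_ll_rate_factor: float = 0.7,
    ca_free_residual: float | None = None,
) -> list[CellEvents]:
    """Transform event programs for a pharmacological intervention window."""
    if kind not in ("nifedipine", "ca_free"):
        raise ValueError(f"unknown intervention {kind!r}; valid kinds: ('nifedipine', 'ca_free')")
    out = []
    residual = params.ca_free_residual if ca_free_residual is None else ca_free_residual
    for i, ev in enumerate(programs):
        rng = _cell_rng(seed, i, _S_INTERVENTION)
        e = replace(
            ev,
            spont=list(ev.spont),
            spike_times=ev.spike_times.copy(),
            spike_amps=ev.spike_amps.copy(),
        )
        if kind == "nifedipine":
            ll = bool(truth.long_lasting[i])
            amp_f = nif_ll_amp_factor if ll else nif_amp_factor
            rate_f = nif_ll_rate_factor if ll else nif_rate_factor
            if len(e.spike_times):
                inside = (e.spike_times >= window.start) & (e.spike_times < window.end)
                u = rng.random(len(e.spike_times))
                drop = inside & (u >= rate_f) & (np.arange(len(e.spike_times)) > 0)
                e.spike_amps = np.where(inside, e.spike_amps * amp_f, e.spike_amps)
                e.spike_times = e.spike_times[~drop]
                e.spike_amps = e.spike_amps[~drop]
            if e.plateau_onset is not None and window.contains(e.plateau_onset):
                e.peak_amp *= amp_f
                e.spike_amps = e.spike_amps * amp_f
            e.spont = [
                (t, a * amp_f) if window.contains(t) else (t, a)
                for t, a in e.spont
                if not (window.contains(t) and rng.random() >= rate_f)
            ]
        else:  # ca_free: responses of extracellular origin vanish in-window
            e.spont = [(t, a) for t, a in e.spont if not window.contains(t)]
            if e.kcl_time is not None and window.contains(e.kcl_time):
                e.kcl_amp = e.kcl_amp * residual
            if len(e.spike_times):
                inside = (e.spike_times >= window.start) & (e.spike_times < window.end)
                amps = np.where(inside, e.spike_amps * residual, e.spike_amps)
                keep = amps > 1e-9
                e.spike_times = e.spike_times[keep]
                e.spike_amps = amps[keep]
            if e.plateau_onset is not None and window.contains(e.plateau_onset):
                e.peak_amp *= residual
        out.append(e)
    return out


def synth_recording(
    group: str,
    n_cells: int,
    seed,
    protocol: StimulusProtocol | None = None,
    params: GroupParams | None = None,
    animal_id: str | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Simulate one animal's recording.

    Deterministic: identical ``(group, n_cells, seed, protocol, params)``
    give bit-identical output, and per-cell substreams mean the first k cells
    do not change when ``n_cells`` grows.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    spec = RecordingSpec(group, n_cells, seed, protocol, params, animal_id)
    proto, p, animal = spec.resolve()
    truth, programs = draw_ground_truth(p, n_cells, seed, proto)
    return _render_recording(programs, truth, p, proto, seed, animal), truth


def _render_recording(programs, truth, params, proto, seed, animal) -> RawRecording:
    cols = []
    for i, ev in enumerate(programs):
        rng = _cell_rng(seed, i, _S_NOISE)
        f0 = rng.uniform(80.0, 120.0)
        cols.append(render_cell(ev, params, proto, rng, f0=f0))
    F = np.column_stack(cols)
    return RawRecording(protocol=proto, animal_id=animal, F=F, roi_ids=tuple(truth.cell_ids))


def apply_intervention(
    spec: RecordingSpec, kind: str, window: Epoch | tuple[float, float], **options
) -> tuple[RawRecording, GroundTruth]:
    """Regenerate a recording with an intervention applied over ``window``.

    ``nifedipine`` thins oscillations and scales amplitudes by factors < 1
    (weaker suppression for long-lasting cells); ``ca_free`` removes
    spontaneous events and the KCl response inside the window, scales evoked
    activity down to the group's residual, and leaves activity outside the
    window untouched (so long-lasting trains recover after washout).
    Factors of 1.0 (or residual 1.0) leave the recording bit-identical.
    """
    win = window if isinstance(window, Epoch) else Epoch(*window)
    proto, params, animal = spec.resolve()
    total = proto.total_time
    if not (0.0 <= win.start and win.end <= total + 1e-9):
        raise ValueError(f"intervention window [{win.start}, {win.end}) outside recording [0, {total})")
    truth, programs = draw_ground_truth(params, spec.n_cells, spec.seed, proto)
    programs = _apply_transform(
        programs, truth, kind, win, params, spec.seed, proto, **options
    )
    proto_i = proto.with_intervention(kind, win)
    rec = _render_recording(programs, truth, params, proto_i, spec.seed, animal)
    return rec, truth


def long_lasting_fixture(
    n_spikes: int,
    seed: int = 1,
    protocol: StimulusProtocol | None = None,
    params: GroupParams | None = None,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """One long-lasting oscillatory trace with an exact ground-truth spike
    count (noise-free and bleach-free by default).

    The train starts just after GnRH onset and runs to the recording end;
    useful for validating the transient detector against a known count.
    """
    proto = protocol if protocol is not None else make_protocol()
    p = (params if params is not None else default_group_params("Cd56")).with_(
        noise_sd=noise_sd, bleach_rate=0.0
    )
    rng = np.random.default_rng(seed)
    onset = proto.gnrh.start + rng.uniform(1.0, 3.0)
    dur = proto.total_time - 5.0 - onset
    ts = _spike_train(rng, onset, dur, n_spikes)
    amp = p.mif_mean - 1.0
    lo, hi = p.osc_amp_range
    amps = np.maximum(SPIKE_AMP_FLOOR, amp * rng.uniform(lo, hi, size=n_spikes))
    amps[0] = amp
    ev = CellEvents(pattern="oscillatory", peak_amp=amp, spike_times=ts, spike_amps=amps)
    return render_cell(ev, p, proto, np.random.default_rng(seed + 1))


# ---------------------------------------------------------------------------
# disk round trip


def write_recording(rec: RawRecording, truth: GroundTruth | None, outdir: str | Path) -> Path:
    """Write a recording to ``<outdir>/<animal>.csv`` plus a JSON sidecar.

    The CSV has a leading ``time_s`` column; the sidecar stores the protocol
    and, when available, the ground-truth labels.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{rec.animal_id}.csv"
    df = pd.DataFrame(rec.F, columns=list(rec.roi_ids))
    df.insert(0, "time_s", rec.protocol.times())
    df.to_csv(csv_path, index=False, float_format="%.6f")

    sidecar = {"animal_id": rec.animal_id, "protocol": rec.protocol.to_dict()}
    if truth is not None:
        sidecar["ground_truth"] = {
            "cell_ids": truth.cell_ids,
            "viable": truth.viable.tolist(),
            "is_gonadotroph": truth.is_gonadotroph.tolist(),
            "pattern": truth.pattern,
            "n_spikes_true": truth.n_spikes_true.tolist(),
            "long_lasting": truth.long_lasting.tolist(),
            "spont_event_times": [t.tolist() for t in truth.spont_event_times],
        }
    with open(outdir / f"{rec.animal_id}.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return csv_path


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        d = json.load(fh)["ground_truth"]
    return GroundTruth(
        cell_ids=d["cell_ids"],
        viable=np.array(d["viable"]),
        is_gonadotroph=np.array(d["is_gonadotroph"]),
        pattern=d["pattern"],
        n_spikes_true=np.array(d["n_spikes_true"]),
        long_lasting=np.array(d["long_lasting"]),
        spont_event_times=[np.array(t) for t in d["spont_event_times"]],
    )
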