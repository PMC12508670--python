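# Methods

This note documents the models, conventions and numerical choices behind
`gonadotrace`, in the order the data flow through the pipeline.

## Recording model and stimulus protocol

A recording is a uniformly sampled fluorescence matrix (frames × ROIs),
0.2 s per frame by default, partitioned into ordered epochs on one time
base: a 240 s **baseline** (the 4-minute epoch over which spontaneous
activity is scored), a 30 s **GnRH pulse** (10 nM in the emulated
experiment), a **washout**, and a terminal 30 s **KCl pulse** used as the
viability gate.  The default protocol is 480 s (2,400 frames) so the full
4-minute baseline fits before stimulation; a shorter geometry (e.g. the
1,000-frame / 200 s preset) is supported, with the baseline truncated and a
warning logged, since a 200 s recording cannot contain both a 4-minute
basal epoch and the stimuli.  Intervention windows (nifedipine,
extracellular-Ca²⁺-free) may overlay the washout/KCl phase.

## Synthetic-recording generator

Each cell's trace is

```
F(t) = F0 · exp(−λ·t) · (1 + r(t)) + ε(t)
```

with F0 ~ U(80, 120) a.u., bleaching rate λ = 5×10⁻⁴ s⁻¹ (≈ 21% signal loss
over 480 s, typical of mild photobleaching), ε white Gaussian noise with SD
0.002·F0, and r(t) ≥ 0 a sum of transient kernels.  Kernels are double
exponentials (rise τ = 0.5 s, decay τ = 3 s; shorter for dense spike
trains, see below) renormalized on the sampling grid so the drawn amplitude
is attained exactly at a sampled frame.

Per-cell labels are drawn from the group's calibration parameters
(`gonadotrace.params`): viability (10% of cells fail the KCl gate by
default), gonadotroph identity (= GnRH responsiveness), spontaneous
activity, response pattern, long-lasting status and spike count.  Each cell
uses independent, counter-derived random substreams, so recordings are
bit-reproducible and the first k cells do not change when more cells are
requested.

Waveform classes:

* **Oscillatory** — n spikes (n drawn per group, see below), the first at
  the response onset carrying the cell's peak amplitude A, later spikes at
  U(lo, hi)·A with a floor of 0.12 so every true spike clears the detector
  threshold.  Inter-spike intervals are gamma-jittered and rescaled to the
  train duration with a floor of max(1.5 s, half the mean interval); the
  floor keeps consecutive kernels resolvable at 0.2 s sampling and their
  troughs deep enough for the prominence criterion.  Kernel decay adapts to
  the train density (τ_d = min(3 s, 0.35·mean ISI)).  Canonical trains
  stretch with the spike count up to 105 s past GnRH offset — 15 s clear of
  the long-lasting rule; long-lasting trains run to the recording end and
  are guaranteed one spike inside the KCl window (these cells oscillate
  through the depolarization instead of showing a discrete KCl peak).
* **Biphasic** — a fast kernel and a slow plateau kernel (rise 3 s, hold
  `plateau_dur`, decay 10 s) mixed 55:45 and renormalized so the composite
  peak equals A; the sum is monotone after the peak, so the trace has a
  single detected peak.
* **Transitory** — one small kernel, amplitude U(0.12, 0.18).

All viable cells except long-lasting ones receive a KCl kernel
(amplitude U(0.4, 0.8), decay 6 s).  Spontaneous transients are Poisson in
the baseline (1.5 events/min for spontaneously active cells, amplitudes
U(0.12, 0.25), ≥ 8 s apart, none in the last 15 s of baseline so their
tails cannot leak into the response window).  Ground truth for
"spontaneously active" is the realized event list, not the Bernoulli draw.

### Spike-count distribution

Counts are negative binomial matched to the group mean/SD and truncated at
≥ 2: the reported group minima are 2–5 spikes, and a one-spike "oscillatory"
cell is definitionally unclassifiable as oscillatory.  For the Cd21 group
the reported SD (0.71) is smaller than the mean (5.50), so no negative
binomial exists; a rounded normal clipped at ≥ 2 is used instead.  Counts
are additionally capped at the train's resolvable capacity
(1 + 0.9·duration/1.5 s); this matters only in the far tail of the Cd56
distribution (see Limitations).

### Calibration

Population parameters (responder/spontaneous fractions, pattern mixtures,
spike-count moments, MIF means/SDs, AUC targets) are the published group
statistics, entered verbatim.  Waveform shape parameters that no publication
reports — plateau duration, secondary spike amplitude range — plus a small
per-group amplitude offset (`amp_cal`, 0.028–0.042) were fixed by a one-off
calibration so that the *pipeline-measured* MIF and AUC means land on the
group targets.  The offset compensates the measurement chain's upward bias:
dividing by a noisy minimum inflates ΔF/F by ≈ 1%, noise adds to the window
maximum, and the amplitude floor truncates the low tail.  Calibration used
simulation seeds disjoint from any test seed.

### Interventions

`apply_intervention` transforms the per-cell event program before
rendering.  *Nifedipine* (L-type Ca²⁺ channel blocker) thins spikes
(keep probability 0.3) and scales amplitudes (×0.4) inside the window, with
weaker suppression (0.7 / 0.75) for long-lasting cells, matching the
observation that long-lasting oscillations are reduced but not abolished.
*Ca²⁺-free* removes spontaneous events and the KCl response inside the
window and scales evoked spikes to a per-group residual (0 for control and
Cd21 — complete loss; 0.25 for Cd35/Cd56 — small residual transients);
events after the window are untouched, so activity recovers when Ca²⁺
returns.  Unit factors reproduce the unperturbed recording bit-for-bit.
The KCl viability gate must be disabled for Ca²⁺-free paradigms (no cell
can respond to depolarization without extracellular Ca²⁺); the pipeline
does this automatically for paired Ca²⁺-free runs.

## Preprocessing

**Detrending.**  Photobleaching is corrected per ROI with a two-pass
single-exponential fit restricted to the pre-stimulus epoch (evoked
activity never enters the fit): a running 10th-percentile baseline (20 s
window) gives a coarse decay rate; the trace is flattened with it, quiet
frames are selected as those within 0.2% of the flattened 10th-percentile
floor, and the final rate comes from a log-linear fit on quiet frames only.
The trace is divided by the fitted curve and rescaled to its initial value
(equivalently multiplied by e^{b̂t}).  A trace in the exact model class is
recovered to machine-level accuracy; transient tails cannot tilt the fit
because they are excluded by the quiet-frame band.  If the percentile
baseline is non-positive the code falls back to a linear fit with a logged
warning, and to the identity if that is degenerate.

**Normalization.**  ΔF/F = F/F_min with F_min taken over the whole
detrended trace; the output minimum is exactly 1.0 and the operation is
idempotent.  F_min is computed after slope correction (whether the original
analysis took it before or after is unstated; after is the choice here, and
positive transients cannot move a minimum).

**Viability gate.**  An ROI is retained iff its detrended ΔF/F exceeds
1 + θ_KCl (θ_KCl = 0.10, reusing the 10%-of-F_min criterion) inside the KCl
window.  Retained cells are the 100% denominator for all fractions.

## Event detection and metrics

Transients are local maxima with ΔF/F − 1 ≥ 0.10 ("greater than 10% of
F_min" is exactly this under ΔF/F = F/F_min), prominence ≥ 0.05 and
separation ≥ 1 s (scipy `find_peaks`).  Spontaneous activity = ≥ 1 transient
in the first 240 s of baseline.  GnRH responder = ΔF/F − 1 ≥ 0.10 anywhere
between GnRH onset and 10 s before KCl onset (the guard keeps the
depolarization response out of GnRH metrics).  MIF and AUC are computed on
a 160 s window from GnRH onset: no window length is reported anywhere, and
160 s is consistent with the printed AUC magnitudes (the window is config).
AUC integrates max(ΔF/F − 1, 0) by the trapezoid rule, including the sample
at the right window edge so AUC is exactly additive over windows sharing a
boundary.  Oscillation counts use the full guarded response window, or the
window extended to the recording end for long-lasting cells.

## Pattern classification

A deterministic decision tree over the response window:

1. **oscillatory** if ≥ 2 peaks and the median inter-peak trough is below
   0.5 × the maximum amplitude — troughs returning toward baseline are the
   defining oscillatory feature, which is also why this rule wins ties over
   the biphasic rule;
2. else **biphasic** if ΔF/F − 1 stays ≥ 0.3 × max amplitude for ≥ 30 s
   contiguously from/after the first peak;
3. else **transitory**.

All thresholds are config-exposed (`ClassifyParams`); the numeric values
are this package's operationalization of a visual classification, not a
claim about the original scorers' criteria.  "Subumbral" (a term used in
earlier literature) and "transitory" are treated as one low-amplitude
single-transient class.  **Long-lasting** = any spike later than 120 s
after GnRH offset (excluding the KCl epoch, whose single depolarization
peak is expected) or ≥ 2 spikes inside the KCl window.  Long-lasting status
is generated only for oscillatory cells: a biphasic cell that resumes
spiking inside the response window would satisfy the oscillatory rule, so a
"long-lasting biphasic" class cannot be recovered by any threshold-based
classifier and is deliberately not simulated.

## Population analysis and aggregation

Synchrony is the zero-lag Pearson correlation of responder pairs over the
response window ("cross-correlation" in the imaging-figure sense of a
static cell × cell similarity matrix); a lagged variant (max over ± 5 s) is
available behind a flag.  Whether the original matrices used raw F or ΔF/F
is unstated; ΔF/F is used here (Pearson r is invariant to the affine part
of the difference).  Constant traces get r = 0 by convention, logged.

Per-animal summaries use: retained cells as denominator for the responder
fraction; responders as denominator for spontaneous/pattern/long-lasting
fractions and for MIF/AUC means; oscillatory-classified cells for the
spike-count mean.  Group statistics are the mean ± SD (n−1) of per-animal
means — the animal is the experimental unit; a test guards against the
pooled-cell-mean bug.  Single-animal groups report SD as missing.

## Statistics

* **Kruskal–Wallis** H with midrank tie correction, p from χ²(k−1)
  (delegated to scipy; all-identical data returns H = 0, p = 1).
* **Dunn's post hoc**: z = (mean-rank difference)/SE with tie-corrected
  SE = √[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ)], two-sided normal
  p-values, Holm step-down across all pairs within one metric.
* **Holm**: sort ascending, multiply p₍ᵢ₎ by (m−i+1), enforce the running
  maximum, cap at 1.
* **Wilcoxon signed-rank**, two-sided, zero differences dropped: exact by
  enumeration of all 2ⁿ sign patterns (midranks, so ties are handled) for
  n ≤ 12; otherwise normal approximation with continuity correction (±0.5)
  and tie-corrected variance.  The statistic is the smaller signed-rank sum.
* Significance stars at 0.05/0.01/0.001/0.0001.

All tests are validated against independent brute-force oracles (rank
formulas from first principles, full sign-pattern enumeration) and the
Kruskal–Wallis test's type-I error is checked at 10⁴ null replicates with
4 groups of 30 (group size 30 keeps the χ² reference in its asymptotic
regime; at n = 10 the H test is intrinsically conservative, rejecting at
≈ 4.2%).

## qPCR

Comparative 2^−ΔΔCt: technical replicates averaged in Ct space, ΔCt =
Ct(target) − Ct(housekeeping) per sample, ΔΔCt relative to the reference
condition's mean ΔCt, fold = 2^−ΔΔCt.  With a single housekeeping gene the
"geometric mean expression" normalization reduces exactly to the arithmetic
mean of its Ct replicates (geometric mean in expression space = arithmetic
mean in Ct space).  The geometric mean of reference-condition folds is
exactly 1.  No amplification-efficiency (Pfaffl) correction.

## What the generator does and does not emulate

It emulates trace-level phenomenology: epoch structure, bleaching, shot-like
noise, spontaneous transients, the three response waveforms, long-lasting
activity, KCl responses, and the published group-level statistics.  It does
**not** model the underlying membrane/ER oscillator dynamics (no ODEs), ROI
segmentation or pixel data, motion artifacts, baseline drift other than
exponential bleaching, cell-to-cell communication (traces are independent
given their labels, so absolute synchrony values are not calibrated — only
contrasts such as Cd21's homogeneity are meaningful), or within-animal
correlation beyond the shared parameters.  Passing tests therefore show the
analysis chain is unbiased on data with these statistics, not that it is
robust to every artifact of real recordings.

## Known limitations

* Cd21's recovered MIF is ≈ 1.13 vs the 1.12 target: the response-amplitude
  floor (0.11) that keeps every generated responder above the 0.10
  detection threshold truncates the low half of the N(0.12, 0.05)
  amplitude distribution.
* Cd56's recovered oscillation count is ≈ 52–58 vs the 64.6 target: the
  resolvability cap limits how many spikes fit in a canonical train; the
  140-spike long-lasting maximum is unaffected.
* The truncated negative binomial slightly inflates the Cd35 mean spike
  count (≈ +7%).
* Classification agreement vs ground truth is 100% noise-free and ≥ 99.5%
  at the default noise level; heavier noise would require retuning the
  prominence threshold.

## Problem sizes

The test suite and the reproduction script use cohorts of 5–6 animals with
60–300 cells per animal (matching the published animal counts and the order
of magnitude of analyzed cells per animal), 10⁴ draws for label-proportion
and null-calibration checks.  The full suite runs in well under a minute of
compute for the simulations plus a few seconds for the statistics checks.
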