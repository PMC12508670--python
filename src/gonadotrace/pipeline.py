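"""End-to-end orchestration: simulate -> preprocess -> events -> classify ->
population -> stats.

`run_experiment` simulates a multi-group, multi-animal study with the
calibrated generator, pushes every recording through the full analysis
chain, aggregates per-animal summaries into group statistics, runs the
Kruskal-Wallis / Dunn-Holm comparisons, and reports a side-by-side
comparison of the recovered group statistics against the generator's
calibration targets.  Everything is deterministic given the master seed:
animal a of group g uses the counter-derived seed (seed, g, a).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import population as pop
from .classify import ClassifyParams, classify_pattern
from .params import GROUPS, GroupParams, default_group_params
from .preprocess import EmptyRecordingError, viability_filter
from .protocol import StimulusProtocol, make_protocol, response_window
from .stats import stat_table, wilcoxon_signed_rank
from .synth import Epoch, GroundTruth, RawRecording, RecordingSpec, apply_intervention, synth_recording

logger = logging.getLogger(__name__)

STAT_METRICS = ("frac_responder", "frac_spontaneous", "frac_oscillatory", "mif", "auc", "n_oscillations")


@dataclass
class ExperimentConfig:
    """Serializable description of one simulated experiment."""

    animals_per_group: dict = field(
        default_factory=lambda: {"control": 6, "Cd21": 5, "Cd35": 6, "Cd56": 6}
    )
    n_cells: int = 200
    seed: int = 1
    protocol: dict = field(default_factory=dict)
    theta_resp: float = 0.10
    theta_kcl: float = 0.10
    theta_amp: float = 0.10
    min_prominence: float = 0.05
    metric_duration: float = 160.0
    kcl_gate: bool = True
    param_overrides: dict = field(default_factory=dict)  # group -> {field: value}
    outdir: str | None = None

    def resolve_protocol(self) -> StimulusProtocol:
        return make_protocol(**self.protocol)

    def resolve_params(self, group: str) -> GroupParams:
        p = default_group_params(group)
        if group in self.param_overrides:
            p = p.with_(**self.param_overrides[group])
        return p

    def classify_params(self) -> ClassifyParams:
        return ClassifyParams(theta_amp=self.theta_amp, min_prominence=self.min_prominence)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class ExperimentResult:
    cells: pd.DataFrame
    animals: pd.DataFrame
    groups: pd.DataFrame
    stats: pd.DataFrame
    comparison: pd.DataFrame
    correlations: dict
    n_failures: int = 0


def analyze_recording(
    recording: RawRecording,
    truth: GroundTruth | None = None,
    config: ExperimentConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series, pop.CorrelationMatrix | None]:
    """Run the full per-recording analysis chain.

    Returns the per-cell result table (viability-gated cells only), the
    per-animal summary row, and the responder correlation matrix (None when
    fewer than two responders survive).
    """
    cfg = config or ExperimentConfig()
    proto = recording.protocol
    norm = viability_filter(recording, theta_kcl=cfg.theta_kcl, gate=cfg.kcl_gate)
    cparams = cfg.classify_params()

    rows = []
    resp_cols = []
    for j, roi in enumerate(norm.roi_ids):
        dff = norm.dff[:, j]
        responder = ev.is_gnrh_responder(dff, proto, theta_resp=cfg.theta_resp)
        pattern, ll = None, False
        if responder:
            label = classify_pattern(dff, proto, cparams)
            pattern, ll = label.pattern, label.long_lasting
            resp_cols.append(j)
        m = ev.cell_metrics(
            dff, proto, cell_id=roi, long_lasting=ll,
            metric_duration=cfg.metric_duration, theta_resp=cfg.theta_resp,
        )
        rows.append(
            {
                "animal": recording.animal_id,
                "cell_id": roi,
                "responder": responder,
                "spontaneous": m.spontaneous,
                "pattern": pattern,
                "long_lasting": ll,
                "mif": m.mif,
                "auc": m.auc,
                "n_oscillations": m.n_oscillations,
            }
        )
    cells = pd.DataFrame(rows)

    R = None
    mean_r = np.nan
    if len(resp_cols) >= 2:
        R = pop.correlation_matrix(
            norm.dff[:, resp_cols],
            response_window(proto),
            proto.dt,
            cell_ids=tuple(norm.roi_ids[j] for j in resp_cols),
        )
        mean_r = pop.mean_pairwise_correlation(R)

    truth_df = truth.to_frame() if truth is not None else None
    summary = pop.summarize_recording(cells, truth=truth_df, mean_correlation=mean_r)
    return cells, summary, R


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentResult:
    """Simulate and analyze the full multi-group experiment."""
    cfg = config or ExperimentConfig()
    proto = cfg.resolve_protocol()
    all_cells, animal_rows, correlations = [], [], {}
    n_failures = 0

    for gi, (group, n_animals) in enumerate(cfg.animals_per_group.items()):
        params = cfg.resolve_params(group)
        for ai in range(n_animals):
            animal_id = f"{group}-a{ai + 1}"
            seed = [cfg.seed, gi, ai]
            try:
                rec, truth = synth_recording(
                    group, cfg.n_cells, seed, protocol=proto, params=params, animal_id=animal_id
                )
                cells, summary, R = analyze_recording(rec, truth, cfg)
            except EmptyRecordingError as exc:
                logger.error("animal %s failed: %s", animal_id, exc)
                n_failures += 1
                continue
            logger.info(
                "analyzed %s: %d cells, %d responders",
                animal_id, summary["n_cells"], summary["n_responders"],
            )
            all_cells.append(cells.assign(group=group))
            summary["group"] = group
            summary["animal"] = animal_id
            animal_rows.append(summary)
            if R is not None:
                correlations[animal_id] = R

    cells = pd.concat(all_cells, ignore_index=True)
    animals = pd.DataFrame(animal_rows).reset_index(drop=True)
    groups = pop.aggregate_groups(animals)
    tables = []
    for m in STAT_METRICS:
        if m not in animals.columns:
            continue
        populated = animals.groupby("group")[m].apply(lambda v: v.notna().any())
        if populated.sum() < 2:
            logger.info("metric %s has data in < 2 groups; skipping tests", m)
            continue
        tables.append(stat_table(animals, m))
    stats = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    comparison = _compare_to_calibration(groups, cfg)

    result = ExperimentResult(cells, animals, groups, stats, comparison, correlations, n_failures)
    if cfg.outdir:
        _write_results(result, cfg)
    return result


def _compare_to_calibration(groups: pd.DataFrame, cfg: ExperimentConfig) -> pd.DataFrame:
    """Recovered group means next to the generator calibration targets."""
    target_of = {
        "frac_responder": lambda p: p.frac_responder,
        "frac_spontaneous": lambda p: p.frac_spontaneous,
        "frac_oscillatory": lambda p: p.pattern_mix[0],
        "frac_biphasic": lambda p: p.pattern_mix[1],
        "frac_transitory": lambda p: p.pattern_mix[2],
        "mif": lambda p: p.mif_mean,
        "auc": lambda p: p.auc_target,
        "n_oscillations": lambda p: p.spike_count_mean,
    }
    rows = []
    for _, r in groups.iterrows():
        fn = target_of.get(r["metric"])
        if fn is None:
            continue
        p = cfg.resolve_params(r["group"])
        target = fn(p)
        rows.append(
            {
                "group": r["group"],
                "metric": r["metric"],
                "recovered": r["mean"],
                "target": target,
                "abs_error": abs(r["mean"] - target) if np.isfinite(r["mean"]) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def run_paired_intervention(
    group: str,
    kind: str,
    window: tuple[float, float] | Epoch,
    n_animals: int = 6,
    n_cells: int = 60,
    seed: int = 1,
    config: ExperimentConfig | None = None,
    **options,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired control-vs-intervention comparison on matched simulated animals.

    Each animal is simulated twice from the same seed — once untouched, once
    with the intervention applied — and per-animal responder means of AUC,
    MIF and oscillation count are compared with the Wilcoxon signed-rank
    test.  Returns (per-animal paired table, test table).
    """
    cfg = config or ExperimentConfig()
    proto = cfg.resolve_protocol()
    if kind == "ca_free":
        # depolarization in Ca2+-free medium cannot mark viability
        cfg = dataclasses.replace(cfg, kcl_gate=False)
    params = cfg.resolve_params(group)
    rows = []
    for ai in range(n_animals):
        sd = [seed, ai]
        spec = RecordingSpec(group, n_cells, sd, proto, params, f"{group}-a{ai + 1}")
        rec0, truth0 = synth_recording(group, n_cells, sd, proto, params, spec.animal_id)
        rec1, truth1 = apply_intervention(spec, kind, window, **options)
        _, s0, _ = analyze_recording(rec0, truth0, cfg)
        _, s1, _ = analyze_recording(rec1, truth1, cfg)
        for metric in ("auc", "mif", "n_oscillations"):
            rows.append(
                {
                    "animal": spec.animal_id,
                    "metric": metric,
                    "before": s0[metric],
                    "after": s1[metric],
                }
            )
    paired = pd.DataFrame(rows)
    tests = []
    for metric, sub in paired.groupby("metric", sort=False):
        ok = sub.dropna(subset=["before", "after"])
        if len(ok) < 2:
            continue
        r = wilcoxon_signed_rank(ok["before"].to_numpy(), ok["after"].to_numpy())
        tests.append(
            {
                "metric": metric,
                "test": r.test,
                "W": r.statistic,
                "p": r.p,
                "n_pairs": r.n[0],
                "direction": "decrease" if ok["after"].mean() < ok["before"].mean() else "increase",
            }
        )
    return paired, pd.DataFrame(tests)


def _write_results(result: ExperimentResult, cfg: ExperimentConfig) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.cells.to_csv(outdir / "cells.csv", index=False)
    result.animals.to_csv(outdir / "animals.csv", index=False)
    result.groups.to_csv(outdir / "groups.csv", index=False)
    result.stats.to_csv(outdir / "stats.csv", index=False)
    result.comparison.to_csv(outdir / "comparison.csv", index=False)
    for animal, R in result.correlations.items():
        pop.write_correlation(R, outdir / f"correlation_{animal}.csv")
    cfg.to_yaml(outdir / "config.yaml")
    with open(outdir / "run.json", "w") as fh:
        json.dump({"seed": cfg.seed, "n_failures": result.n_failures}, fh)
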