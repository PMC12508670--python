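"""Population synchrony and per-animal / per-group aggregation.

Synchrony is summarized by the zero-lag Pearson correlation of every
responder pair's response-window dF/F segment (a lagged variant maximizing
over +/-5 s is available behind a flag).  Group statistics are computed on
per-animal means — the animal, not the cell, is the statistical unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol, response_window

logger = logging.getLogger(__name__)

#: metrics carried through per-animal summaries and group aggregation
SUMMARY_METRICS = (
    "frac_responder",
    "frac_spontaneous",
    "frac_oscillatory",
    "frac_biphasic",
    "frac_transitory",
    "frac_long_lasting",
    "mif",
    "auc",
    "n_oscillations",
    "mean_correlation",
)


@dataclass(frozen=True)
class CorrelationMatrix:
    cell_ids: tuple[str, ...]
    R: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if self.R.shape != (n, n):
            raise ValueError("R must be square and match cell_ids")
        if not np.allclose(self.R, self.R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-12):
            raise ValueError("R must have a unit diagonal")
        if not np.all(np.isfinite(self.R)):
            raise ValueError("R must be finite")


def correlation_matrix(
    dff_matrix: np.ndarray,
    window: tuple[float, float],
    dt: float,
    cell_ids: tuple[str, ...] | None = None,
    max_lag_s: float = 0.0,
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of response-window segments.

    ``dff_matrix`` is (n_frames, n_cells); at least two cells are required.
    Constant traces get correlation 0 with every partner, by convention.
    With ``max_lag_s > 0`` each pair's coefficient is the maximum Pearson
    correlation over integer-frame lags up to that many seconds.
    """
    X = np.asarray(dff_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a (n_frames, >=2 cells) matrix")
    i0 = max(0, int(np.ceil(window[0] / dt - 1e-9)))
    i1 = min(X.shape[0], int(np.ceil(window[1] / dt - 1e-9)))
    if i1 - i0 < 10:
        raise ValueError(f"window {window} shorter than 10 samples at dt={dt}")
    seg = X[i0:i1]
    n = seg.shape[1]
    ids = cell_ids if cell_ids is not None else tuple(f"cell{j}" for j in range(n))

    sd = seg.std(axis=0)
    constant = sd < 1e-12
    if constant.any():
        logger.warning("%d constant trace(s): correlation set to 0 by convention", constant.sum())

    safe = seg.copy()
    safe[:, constant] = np.random.default_rng(0).normal(size=(seg.shape[0], constant.sum()))
    if max_lag_s <= 0:
        R = np.corrcoef(safe, rowvar=False)
    else:
        L = int(round(max_lag_s / dt))
        z = (safe - safe.mean(axis=0)) / safe.std(axis=0)
        m = z.shape[0]
        R = np.eye(n)
        for a in range(n):
            for b in range(a + 1, n):
                best = -np.inf
                for lag in range(-L, L + 1):
                    if lag >= 0:
                        r = float(np.mean(z[lag:, a] * z[: m - lag, b]))
                    else:
                        r = float(np.mean(z[: m + lag, a] * z[-lag:, b]))
                    best = max(best, r)
                R[a, b] = R[b, a] = best
    R = np.clip(R, -1.0, 1.0)
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    return CorrelationMatrix(cell_ids=tuple(ids), R=R)


def mean_pairwise_correlation(R: CorrelationMatrix | np.ndarray) -> float:
    """Mean of the strict upper triangle of a correlation matrix."""
    M = R.R if isinstance(R, CorrelationMatrix) else np.asarray(R, dtype=float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("mean pairwise correlation is undefined for a single cell")
    iu = np.triu_indices(n, k=1)
    return float(M[iu].mean())


def summarize_recording(
    cells: pd.DataFrame,
    truth: pd.DataFrame | None = None,
    mean_correlation: float = np.nan,
) -> pd.Series:
    """Collapse a per-cell result table (viability-gated cells only) to one
    per-animal summary row.

    Fractions use the KCl-responsive (retained) cells as denominator;
    pattern proportions use GnRH responders as denominator; MIF/AUC are
    averaged over responders and oscillation counts over oscillatory cells.
    With ground truth attached, label-agreement QC columns are added.
    """
    n = len(cells)
    if n == 0:
        raise ValueError("no cells to summarize")
    resp = cells[cells["responder"]]
    n_resp = len(resp)
    out = {
        "n_cells": n,
        "n_responders": n_resp,
        "frac_responder": n_resp / n,
        "frac_spontaneous": float(resp["spontaneous"].mean()) if n_resp else 0.0,
        "mean_correlation": mean_correlation,
    }
    for pat in ("oscillatory", "biphasic", "transitory"):
        out[f"frac_{pat}"] = float((resp["pattern"] == pat).mean()) if n_resp else 0.0
    out["frac_long_lasting"] = float(resp["long_lasting"].mean()) if n_resp else 0.0
    out["mif"] = float(resp["mif"].mean()) if n_resp else np.nan
    out["auc"] = float(resp["auc"].mean()) if n_resp else np.nan
    osc = resp[resp["pattern"] == "oscillatory"]
    out["n_oscillations"] = float(osc["n_oscillations"].mean()) if len(osc) else np.nan

    if truth is not None:
        merged = cells.merge(truth, on="cell_id", suffixes=("", "_true"))
        both = merged[merged["responder"] & merged["is_gonadotroph"]]
        out["responder_agreement"] = float(
            (merged["responder"] == merged["is_gonadotroph"]).mean()
        )
        out["pattern_agreement"] = (
            float((both["pattern"] == both["pattern_true"]).mean()) if len(both) else np.nan
        )
    return pd.Series(out)


def aggregate_groups(summaries: pd.DataFrame) -> pd.DataFrame:
    """Group mean +/- SD over per-animal means.

    ``summaries`` needs ``group`` and ``animal`` columns plus metric columns.
    SD uses the n-1 denominator and is reported as missing for single-animal
    groups.  The group mean is the mean of per-animal means, never a pooled
    cell mean.
    """
    metrics = [m for m in SUMMARY_METRICS if m in summaries.columns]
    rows = []
    for group, sub in summaries.groupby("group", sort=False):
        for m in metrics:
            vals = sub[m].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "group": group,
                    "metric": m,
                    "mean": vals.mean() if len(vals) else np.nan,
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "n_animals": len(vals),
                }
            )
    return pd.DataFrame(rows)


def write_correlation(R: CorrelationMatrix, path: str | Path) -> None:
    pd.DataFrame(R.R, index=list(R.cell_ids), columns=list(R.cell_ids)).to_csv(path)


def plot_correlation_heatmap(R: CorrelationMatrix, path: str | Path) -> None:
    """Optional heatmap export (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(R.R, vmin=-1, vmax=1, cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_xlabel("cell")
    ax.set_ylabel("cell")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
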