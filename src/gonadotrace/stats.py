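"""Nonparametric group statistics.

Multi-group comparisons use the Kruskal-Wallis rank test followed by Dunn's
pairwise post hoc z tests with Holm step-down adjustment; paired designs use
the Wilcoxon signed-rank test with continuity correction (exact sign-pattern
enumeration for n <= 12).  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p: float
    p_adj: float | None = None
    groups: tuple[str, str] | None = None
    n: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        for v in (self.p, self.p_adj):
            if v is not None and not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError(f"p-value {v} outside [0, 1]")


def significance_stars(p: float) -> str:
    """The conventional star coding at 0.05 / 0.01 / 0.001 / 0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Kruskal-Wallis H with midrank tie correction; p from chi2(k-1)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 1 for a in arrs):
        raise ValueError("need >= 2 groups with >= 1 observation each")
    if sum(len(a) for a in arrs) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:  # scipy raises on all-identical data
        return StatResult("kruskal-wallis", 0.0, 1.0, n=tuple(len(a) for a in arrs))
    H, p = sps.kruskal(*arrs)
    return StatResult("kruskal-wallis", float(H), float(p), n=tuple(len(a) for a in arrs))


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment, returned in the input order.

    Sort ascending, multiply p_(i) by (m - i), enforce the running maximum,
    cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.maximum.accumulate(p[order] * (m - np.arange(m)))
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    adjust: str = "holm",
    labels: Sequence[str] | None = None,
) -> list[StatResult]:
    """Dunn's pairwise mean-rank z tests after Kruskal-Wallis.

    z = (mean-rank difference) / SE with the tie-corrected SE
    sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)), T = sum(t^3 - t)/(12(N-1));
    two-sided normal p-values, Holm-adjusted across all pairs.
    """
    if adjust not in ("holm", "none"):
        raise ValueError("adjust must be 'holm' or 'none'")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need >= 2 groups")
    names = list(labels) if labels is not None else [f"g{i}" for i in range(len(arrs))]
    pooled = np.concatenate(arrs)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(a) for a in arrs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term

    results = []
    zs, ps, pairs = [], [], []
    for i, j in combinations(range(len(arrs)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        zs.append(float(z))
        ps.append(min(p, 1.0))
        pairs.append((names[i], names[j]))
    adj = holm_adjust(ps) if adjust == "holm" else [None] * len(ps)
    for z, p, pa, pair, (i, j) in zip(zs, ps, adj, pairs, combinations(range(len(arrs)), 2)):
        results.append(
            StatResult(
                "dunn",
                z,
                p,
                p_adj=None if pa is None else float(pa),
                groups=pair,
                n=(sizes[i], sizes[j]),
            )
        )
    return results


def _wilcoxon_exact(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p by enumeration of all sign patterns of |d| midranks."""
    n = len(ranks)
    total = ranks.sum()
    signs = np.array(np.meshgrid(*([[0.0, 1.0]] * n))).T.reshape(-1, n)
    wplus = signs @ ranks
    lo = np.sum(wplus <= w_obs + 1e-9)
    hi = np.sum(wplus >= total - w_obs - 1e-9)
    return float(min(1.0, (lo + hi) / len(wplus)))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped before ranking.  For n <= 12 the p-value is
    computed by exact enumeration of the 2^n sign patterns (midranks, so ties
    in |d| are handled); otherwise by the normal approximation with
    continuity correction (+/- 0.5) and tie-corrected variance.  The reported
    statistic W is the smaller of the two signed-rank sums.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return StatResult("wilcoxon", 0.0, 1.0, n=(0,))
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)
    if n <= 12:
        p = _wilcoxon_exact(ranks, W)
    else:
        mean = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(counts**3 - counts) / 48.0
        # continuity correction pulls |W - mean| toward 0 by 0.5
        z = (abs(W - mean) - 0.5) / np.sqrt(var) if var > 0 else 0.0
        p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return StatResult("wilcoxon", W, p, n=(n,))


def stat_table(
    per_animal: pd.DataFrame, metric: str, group_col: str = "group"
) -> pd.DataFrame:
    """Kruskal-Wallis + Dunn/Holm table for one metric across groups."""
    groups, labels = [], []
    for g, sub in per_animal.groupby(group_col, sort=False):
        vals = sub[metric].dropna().to_numpy(dtype=float)
        if len(vals):
            groups.append(vals)
            labels.append(str(g))
    kw = kruskal_wallis(groups)
    rows = [
        {
            "metric": metric,
            "test": kw.test,
            "comparison": "all",
            "statistic": kw.statistic,
            "p": kw.p,
            "p_adj": np.nan,
            "stars": significance_stars(kw.p),
        }
    ]
    for r in dunn_posthoc(groups, adjust="holm", labels=labels):
        rows.append(
            {
                "metric": metric,
                "test": r.test,
                "comparison": f"{r.groups[0]} vs {r.groups[1]}",
                "statistic": r.statistic,
                "p": r.p,
                "p_adj": r.p_adj,
                "stars": significance_stars(r.p_adj),
            }
        )
    return pd.DataFrame(rows)
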