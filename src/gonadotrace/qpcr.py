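"""Comparative 2^-ddCt relative gene expression from qPCR Ct tables.

Technical replicates are averaged in Ct space (for a single housekeeping
gene, a geometric mean of expression is exactly an arithmetic mean of Ct),
each target is normalized to the housekeeping gene within its sample
(dCt = Ct_target - Ct_housekeeping, removing plate offsets), and expression
is reported relative to the reference condition's mean dCt:
fold = 2^-(dCt_sample - mean dCt_reference).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "condition", "gene", "replicate", "ct")


class CtTableError(ValueError):
    pass


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return validate_ct_table(df)


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise CtTableError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any() or table["ct"].isna().any():
        raise CtTableError("Ct values must be positive and non-missing")
    return table


def ddct_fold_change(
    table: pd.DataFrame,
    housekeeping: str = "Rpl19",
    reference_condition: str = "control",
) -> pd.DataFrame:
    """Per-sample relative expression by the comparative 2^-ddCt method.

    Returns one row per (sample, gene != housekeeping) with columns
    ``dct``, ``ddct``, ``fold`` and ``log2_fold``.  The geometric mean of
    the reference condition's fold changes is exactly 1 for every gene.
    """
    table = validate_ct_table(table)
    mean_ct = (
        table.groupby(["sample", "condition", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    hk = mean_ct[mean_ct["gene"] == housekeeping].set_index("sample")["ct"]
    targets = mean_ct[mean_ct["gene"] != housekeeping].copy()
    missing = sorted(set(targets["sample"]) - set(hk.index))
    if missing:
        raise CtTableError(
            f"housekeeping gene {housekeeping!r} missing for sample(s): {missing}"
        )
    if reference_condition not in set(table["condition"]):
        raise CtTableError(f"reference condition {reference_condition!r} not present")

    targets["dct"] = targets["ct"].to_numpy() - hk.loc[targets["sample"]].to_numpy()
    ref_dct = (
        targets[targets["condition"] == reference_condition]
        .groupby("gene")["dct"]
        .mean()
    )
    genes_wo_ref = sorted(set(targets["gene"]) - set(ref_dct.index))
    if genes_wo_ref:
        raise CtTableError(
            f"no {reference_condition!r} samples for gene(s): {genes_wo_ref}"
        )
    targets["ddct"] = targets["dct"] - ref_dct.loc[targets["gene"]].to_numpy()
    targets["fold"] = 2.0 ** (-targets["ddct"])
    targets["log2_fold"] = -targets["ddct"]
    return targets[["sample", "condition", "gene", "dct", "ddct", "fold", "log2_fold"]]


def fold_change_matrix(folds: pd.DataFrame, agg: str = "mean") -> pd.DataFrame:
    """Condition x gene matrix of (arithmetic) mean fold changes, heatmap-ready."""
    return folds.pivot_table(index="condition", columns="gene", values="fold", aggfunc=agg)


def write_fold_changes(folds: pd.DataFrame, path: str | Path) -> None:
    folds.to_csv(path, index=False)
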