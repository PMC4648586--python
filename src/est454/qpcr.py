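"""Relative qPCR quantification by the 2^-ddCt method.

Target gene Ct values are normalised against the geometric mean of the
reference-gene quantities — with amplification efficiency fixed at 2 this
is the arithmetic mean of the reference Ct values:

    dCt  = Ct_target - mean(Ct_refs)
    ddCt = mean(dCt_stress) - mean(dCt_control)
    fold change = 2 ** (-ddCt)

Technical replicates are averaged to one Ct per (gene, biological sample)
first; biological replicates are the units of the two-sided t-test between
conditions. The p-value is reported as missing (NaN) when either condition
has fewer than two biological replicates.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionResult",
    "normalize_ct",
    "ddct_fold_change",
    "read_ct_table",
    "relative_expression",
    "significance_stars",
]

CT_COLUMNS = ["gene", "sample", "condition", "tissue", "replicate", "ct"]


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    tissue: str
    fold_change: float
    p_value: float  # NaN when undefined (< 2 replicates in a condition)
    n_replicates: int


def normalize_ct(ct_target: float, ct_refs: Sequence[float]) -> float:
    """dCt of a target against the (geometric-mean-quantity) reference:
    ct_target minus the arithmetic mean of the reference Cts."""
    refs = list(ct_refs)
    if not refs:
        raise ValueError("at least one reference Ct is required")
    return float(ct_target - np.mean(refs))


def ddct_fold_change(
    dct_stress: Sequence[float],
    dct_control: Sequence[float],
    gene: str = "",
    tissue: str = "",
) -> ExpressionResult:
    """Fold change 2^-ddCt of stress vs control with a two-sided t-test on
    the per-replicate dCt values."""
    s = np.asarray(list(dct_stress), dtype=float)
    c = np.asarray(list(dct_control), dtype=float)
    if s.size == 0 or c.size == 0:
        raise ValueError("both conditions need at least one dCt value")
    ddct = s.mean() - c.mean()
    fold = 2.0 ** (-ddct)
    if s.size >= 2 and c.size >= 2:
        p = float(stats.ttest_ind(s, c).pvalue)
    else:
        p = math.nan
    return ExpressionResult(
        gene=gene,
        tissue=tissue,
        fold_change=float(fold),
        p_value=p,
        n_replicates=int(min(s.size, c.size)),
    )


def read_ct_table(path: str | os.PathLike) -> pd.DataFrame:
    """Load a Ct TSV with columns gene, sample, condition, tissue,
    replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def relative_expression(
    ct: pd.DataFrame,
    targets: Sequence[str],
    refs: Sequence[str],
    control: str = "control",
    stress: str = "stress",
) -> list[ExpressionResult]:
    """Per-gene, per-tissue fold change and t-test from a long Ct table.

    Technical replicates (multiple rows per gene and sample) are averaged;
    each biological sample contributes one dCt per target gene.
    """
    refs = list(refs)
    if not refs:
        raise ValueError("at least one reference gene is required")
    present = set(ct["gene"])
    for g in refs:
        if g not in present:
            raise ValueError(f"reference gene {g!r} absent from Ct table")
    # one Ct per (tissue, condition, sample, gene): average technical reps
    mean_ct = (
        ct.groupby(["tissue", "condition", "sample", "gene"])["ct"]
        .mean()
        .reset_index()
    )
    results: list[ExpressionResult] = []
    for tissue, tdf in mean_ct.groupby("tissue", sort=True):
        wide = tdf.pivot_table(
            index=["condition", "sample"], columns="gene", values="ct"
        )
        if wide[refs].isna().any().any():
            raise ValueError(f"reference gene Ct missing in tissue {tissue!r}")
        ref_mean = wide[refs].mean(axis=1)
        for gene in targets:
            if gene not in wide.columns:
                raise ValueError(f"target gene {gene!r} absent from Ct table")
            dct = wide[gene] - ref_mean
            dct = dct.dropna()
            d_stress = dct.loc[stress].to_numpy() if stress in dct.index else []
            d_control = dct.loc[control].to_numpy() if control in dct.index else []
            results.append(
                ddct_fold_change(d_stress, d_control, gene=gene, tissue=str(tissue))
            )
    return results


def significance_stars(p: float) -> str:
    """Conventional star coding: *** p<0.001, ** p<0.01, * p<0.05."""
    if math.isnan(p):
        return ""
    for cut, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < cut:
            return mark
    return ""
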