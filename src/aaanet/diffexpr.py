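"""Differential-expression screening and candidate intersection.

The screen applies the thresholds fold change > 1.5 and BH-adjusted
p < 0.05 to a per-gene DE results table.  The fold-change threshold is
two-sided — a gene passes when max(FC, 1/FC) > 1.5 — since both up- and
down-regulated genes are of interest; both inequalities are strict.

`welch_de` is a per-gene Welch t-test on log2 expression for SYNTHETIC
two-group matrices.  It is a stand-in test for generated data, not a
reimplementation of moderated-t pipelines; real studies should supply a
precomputed DE table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DE_COLUMNS = ["gene", "fold_change", "p", "adj_p"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to <= 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def validate_de_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column names, positivity of FC, probability ranges, uniqueness."""
    missing = {"gene", "fold_change"} - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing column(s): {sorted(missing)}")
    if table["gene"].duplicated().any():
        raise ValueError("DE table contains duplicate genes")
    if (table["fold_change"] <= 0).any():
        raise ValueError("fold_change must be positive (linear scale)")
    if "adj_p" not in table.columns:
        if "p" not in table.columns:
            raise ValueError("DE table needs 'adj_p' or raw 'p' to adjust")
        table = table.copy()
        table["adj_p"] = bh_adjust(table["p"].to_numpy())
    for col in ("p", "adj_p"):
        if col in table.columns and ((table[col] < 0) | (table[col] > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    return table


def welch_de(expr: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-gene Welch t-test on log2 values for a genes x samples matrix.

    ``groups`` maps sample name to "case" or "control".  Fold change is
    reported on the linear scale, 2**(mean log2 case - mean log2 control).
    Genes with identical values in both groups get p = 1.

    Raises on groups with fewer than 2 samples or non-positive expression.
    """
    labels = groups.loc[expr.columns]
    case = expr.columns[labels == "case"]
    ctrl = expr.columns[labels == "control"]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("each group needs >= 2 samples")
    if (expr.to_numpy() <= 0).any():
        raise ValueError("expression values must be positive (linear scale)")
    log2 = np.log2(expr.to_numpy(dtype=float))
    a = log2[:, [expr.columns.get_loc(s) for s in case]]
    b = log2[:, [expr.columns.get_loc(s) for s in ctrl]]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero variance in both groups
    fc = 2.0 ** (a.mean(axis=1) - b.mean(axis=1))
    out = pd.DataFrame(
        {
            "gene": expr.index,
            "fold_change": fc,
            "p": p,
            "adj_p": bh_adjust(p),
        }
    ).reset_index(drop=True)
    return out


def screen_de(
    table: pd.DataFrame,
    fc_threshold: float = 1.5,
    adjp_threshold: float = 0.05,
) -> set[str]:
    """Genes passing max(FC, 1/FC) > fc_threshold AND adj_p < adjp_threshold."""
    if fc_threshold <= 0 or adjp_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if len(table) == 0:
        return set()
    table = validate_de_table(table)
    fc = table["fold_change"].to_numpy(dtype=float)
    two_sided = np.maximum(fc, 1.0 / fc)
    keep = (two_sided > fc_threshold) & (table["adj_p"].to_numpy() < adjp_threshold)
    return set(table.loc[keep, "gene"])


def intersect_candidates(
    candidates: pd.DataFrame, de_genes: set[str]
) -> tuple[set[str], float]:
    """Overlap of called candidates with DE genes, and its fraction of the
    called candidates (0 when nothing is called)."""
    called = set(candidates.loc[candidates["called"], "gene"])
    overlap = called & de_genes
    frac = len(overlap) / len(called) if called else 0.0
    return overlap, frac
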