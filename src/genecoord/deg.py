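"""Two-group differential expression with BH correction.

A deliberately simple stand-in for a full moderated-t workflow: per-gene
log2 fold change as the difference of group means (inputs are assumed to be
on the log2 scale already), a Welch unequal-variance t-test for the p-value,
Benjamini-Hochberg step-up adjustment, and joint |logFC| / p thresholding
into up / down / ns calls.  No variance moderation or covariate adjustment
is attempted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .preprocess import split_by_group

__all__ = [
    "log_fold_change",
    "welch_t_test",
    "benjamini_hochberg",
    "call_degs",
    "differential_expression",
]


def _two_groups(X: ExpressionMatrix, case: str, control: str) -> tuple[np.ndarray, np.ndarray]:
    parts = split_by_group(X)
    for g in (case, control):
        if g not in parts:
            raise ValueError(f"group {g!r} not found; groups are {sorted(parts)}")
    return parts[case].values, parts[control].values


def log_fold_change(X: ExpressionMatrix, case: str, control: str) -> pd.Series:
    """Per-gene mean(case) - mean(control) on the log2 scale."""
    a, b = _two_groups(X, case, control)
    return pd.Series(a.mean(axis=1) - b.mean(axis=1), index=X.gene_ids, name="logFC")


def welch_t_test(X: ExpressionMatrix, case: str, control: str) -> pd.Series:
    """Two-sided Welch t-test p-value per gene (Satterthwaite df).

    Requires >= 2 samples per group.  Genes where both groups are exactly
    constant get p = 1 if the means agree and p = 0 otherwise.
    """
    a, b = _two_groups(X, case, control)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("Welch t-test needs at least two samples per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate zero-variance rows: scipy returns nan
    bad = ~np.isfinite(p)
    if bad.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(bad, np.where(same, 1.0, 0.0), p)
    return pd.Series(p, index=X.gene_ids, name="p_raw")


def benjamini_hochberg(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    For p-values sorted ascending, p_adj at rank i is
    ``min_{j >= i} m * p_(j) / j`` capped at 1.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_degs(
    table: pd.DataFrame,
    lfc_thresh: float = 1.5,
    p_thresh: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Label each gene up / down / ns by strict joint thresholds.

    ``up`` iff logFC > lfc_thresh and p < p_thresh; ``down`` iff
    logFC < -lfc_thresh and p < p_thresh.  ``use_adjusted`` selects the BH
    p_adj column (default) or raw p.
    """
    for col in ("logFC", "p_raw", "p_adj"):
        if col not in table.columns:
            raise ValueError(f"DEG table is missing column {col!r}")
    p = table["p_adj"] if use_adjusted else table["p_raw"]
    lfc = table["logFC"]
    status = np.where(
        (lfc > lfc_thresh) & (p < p_thresh),
        "up",
        np.where((lfc < -lfc_thresh) & (p < p_thresh), "down", "ns"),
    )
    out = table.copy()
    out["status"] = status
    return out


def differential_expression(
    X: ExpressionMatrix,
    case: str,
    control: str,
    lfc_thresh: float = 1.5,
    p_thresh: float = 0.05,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """logFC + Welch p + BH adjustment + status, one row per gene."""
    table = pd.DataFrame(
        {
            "logFC": log_fold_change(X, case, control),
            "p_raw": welch_t_test(X, case, control),
        }
    )
    table["p_adj"] = benjamini_hochberg(table["p_raw"].to_numpy())
    return call_degs(table, lfc_thresh=lfc_thresh, p_thresh=p_thresh, use_adjusted=use_adjusted)
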