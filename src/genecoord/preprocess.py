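"""Gene selection, group splitting and per-gene Z-scoring.

These are the three bookkeeping steps the coordination statistic needs:
restrict to the gene set of interest, split columns by diagnosis group, and
standardize every gene to mean 0 / SD 1 within the matrix it sits in.  The
normalized eigen-spectrum downstream is invariant to the SD divisor (m vs
m-1), so ``ddof`` is exposed but rarely matters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = ["select_genes", "split_by_group", "zscore_rows"]


def select_genes(X: ExpressionMatrix, gene_ids: list[str]) -> ExpressionMatrix:
    """Restrict rows to ``gene_ids``, in the requested order.

    Raises
    ------
    KeyError
        If any requested gene is absent; the message names the culprits.
    """
    missing = [g for g in gene_ids if g not in X.data.index]
    if missing:
        raise KeyError(f"gene(s) not present in matrix: {missing}")
    return ExpressionMatrix(data=X.data.loc[gene_ids], groups=X.groups)


def split_by_group(X: ExpressionMatrix) -> dict[str, ExpressionMatrix]:
    """Partition columns into one submatrix per group label.

    Every sample must carry a label (enforced at construction).  The
    returned submatrices keep the input's column order within each group.
    """
    if X.groups is None:
        raise ValueError("group labels are required to split the matrix")
    out: dict[str, ExpressionMatrix] = {}
    for name in X.group_names():
        cols = [s for s in X.sample_ids if X.groups[s] == name]
        out[name] = ExpressionMatrix(data=X.data[cols], groups=X.groups[cols])
    return out


def zscore_rows(
    X: ExpressionMatrix,
    ddof: int = 1,
    drop_constant: bool = False,
) -> ExpressionMatrix:
    """Standardize each gene to mean 0 and SD 1 across samples.

    Parameters
    ----------
    ddof
        SD divisor is ``m - ddof``; 1 (sample SD) by default.
    drop_constant
        Zero-variance genes are an error by default; set True to silently
        drop them instead (useful on real data with flat probes).
    """
    values = X.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    if flat.any():
        names = [g for g, bad in zip(X.gene_ids, flat) if bad]
        if not drop_constant:
            raise ValueError(f"zero-variance gene(s), cannot Z-score: {names}")
        keep = ~flat
        values, mean, sd = values[keep], mean[keep], sd[keep]
        index = [g for g, ok in zip(X.gene_ids, keep) if ok]
    else:
        index = X.gene_ids
    z = (values - mean) / sd
    data = pd.DataFrame(z, index=index, columns=X.sample_ids)
    return ExpressionMatrix(data=data, groups=X.groups)
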