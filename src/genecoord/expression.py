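"""Gene-by-sample expression container and its TSV dialect.

The on-disk layout is the plain layout most GEO-derived matrices use once
probe handling is done: a TSV whose first column holds gene identifiers and
whose header row holds sample identifiers.  Group membership travels in a
separate two-column TSV (``sample<TAB>group``) so the matrix itself stays a
pure numeric table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of (log-scale) expression values.

    Parameters
    ----------
    data
        DataFrame with gene IDs as the index and sample IDs as columns.
        Values are real, finite, and typically on the log2 scale.
    groups
        Optional mapping sample ID -> group name covering every column.
    """

    data: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene IDs: {dup}")
        if self.data.shape[0] < 1:
            raise ValueError("expression matrix needs at least one gene")
        if self.data.shape[1] < 2:
            raise ValueError("expression matrix needs at least two samples")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains missing or non-finite values")
        if self.groups is not None:
            groups = pd.Series(self.groups)
            groups = groups[groups.notna()]
            unlabeled = [s for s in self.data.columns if s not in groups.index]
            if unlabeled:
                raise ValueError(f"samples without a group label: {unlabeled}")
            # align to column order; drop labels for absent samples
            self.groups = groups.loc[self.data.columns]

    # -- basic views ------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def group_names(self) -> list[str]:
        if self.groups is None:
            raise ValueError("matrix carries no group labels")
        return sorted(self.groups.unique())

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path, label_path: str | Path | None = None) -> None:
        """Write the matrix (and optionally the group table) as TSV."""
        self.data.to_csv(path, sep="\t", index_label="gene_id")
        if label_path is not None:
            if self.groups is None:
                raise ValueError("no group labels to write")
            self.groups.rename("group").to_csv(label_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path, label_path: str | Path | None = None) -> "ExpressionMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        groups = None
        if label_path is not None:
            table = pd.read_csv(label_path, sep="\t", index_col=0)
            groups = table.iloc[:, 0].astype(str)
        return cls(data=data, groups=groups)
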