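"""Eigen-spectrum coordination analysis of a gene set.

The statistic asks how *jointly* a small set of genes co-varies within a
sample group.  Stack the Z-scored expression rows of the n genes into a
matrix Z (n x m over m samples) and form the Gram (inner-product) matrix

    R = Z Z^T,      R_ij = sum_s z_is z_js ,

which, up to the constant SD divisor, is the sample correlation matrix of
the gene set.  Because R is symmetric positive semi-definite it admits an
orthogonal eigendecomposition R = Q diag(lambda) Q^T.  Each eigenvalue is
then normalized by the spectrum total,

    lambda_i  <-  lambda_i / sum_k lambda_k ,

so the spectrum sums to 1 and is invariant to overall scale.  A spectrum
concentrated on the first eigenvalue means the genes move as one block
(tight coordination); a flat spectrum (all 1/n) means independence.
Comparing the two groups' spectra rank by rank quantifies how much more
(or less) coordinated the gene set is in cases than in controls.

For an equicorrelated gene set (common pairwise correlation rho) the
population spectrum is closed form:

    lambda_1 = (1 + (n-1) rho) / n,    lambda_2..n = (1 - rho) / n,

which the test-suite uses as an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix
from .preprocess import select_genes, split_by_group, zscore_rows

__all__ = [
    "GramMatrix",
    "EigenSpectrum",
    "SpectrumComparison",
    "inner_product_matrix",
    "normalized_eigenvalues",
    "compare_spectra",
    "coordination_analysis",
]

# Relative tolerance (x trace) below which a negative eigenvalue is treated
# as floating-point PSD violation and clamped, rather than an error.
_PSD_RTOL = 1e-8


@dataclass
class GramMatrix:
    """Symmetric PSD matrix of pairwise inner products of expression rows."""

    gene_ids: list[str]
    values: np.ndarray
    sample_count: int

    def __post_init__(self) -> None:
        R = np.asarray(self.values, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("Gram matrix must be square")
        if R.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match matrix size")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("Gram matrix is not symmetric within 1e-10")
        self.values = R


@dataclass
class EigenSpectrum:
    """Normalized eigenvalues of a gene-set Gram matrix.

    ``values`` are non-negative, sorted descending and sum to 1; ``group``
    optionally names the sample group the spectrum was computed from.
    """

    values: np.ndarray
    gene_ids: list[str]
    group: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("normalized eigenvalues must lie in [0, 1]")
        if abs(v.sum() - 1.0) > 1e-10:
            raise ValueError("normalized eigenvalues must sum to 1")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("normalized eigenvalues must be non-increasing")
        self.values = v

    @property
    def largest(self) -> float:
        return float(self.values[0])

    @property
    def smallest(self) -> float:
        return float(self.values[-1])

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "gene_ids": list(self.gene_ids),
            "values": [float(x) for x in self.values],
        }


@dataclass
class SpectrumComparison:
    """Rank-wise difference between two groups' normalized spectra.

    ``per_rank_delta[i] = lambda_i(group_b) - lambda_i(group_a)``; because
    both spectra sum to 1 the deltas sum to 0 — coordination gained at the
    top of the spectrum is paid for elsewhere.
    """

    group_a: str
    group_b: str
    spectrum_a: EigenSpectrum
    spectrum_b: EigenSpectrum
    per_rank_delta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        a, b = self.spectrum_a, self.spectrum_b
        if len(a.values) != len(b.values):
            raise ValueError("spectra have different lengths")
        if set(a.gene_ids) != set(b.gene_ids):
            raise ValueError(
                f"spectra describe different gene sets: {a.gene_ids} vs {b.gene_ids}"
            )
        self.per_rank_delta = b.values - a.values

    @property
    def largest_delta(self) -> float:
        """Change in the dominant (rank-1) eigenvalue, b minus a."""
        return float(self.per_rank_delta[0])

    @property
    def smallest_delta(self) -> float:
        """Change in the trailing (rank-n) eigenvalue, b minus a."""
        return float(self.per_rank_delta[-1])

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "spectrum_a": self.spectrum_a.to_dict(),
            "spectrum_b": self.spectrum_b.to_dict(),
            "per_rank_delta": [float(x) for x in self.per_rank_delta],
            "largest_delta": self.largest_delta,
            "smallest_delta": self.smallest_delta,
        }


def inner_product_matrix(
    X: ExpressionMatrix, require_standardized: bool = True
) -> GramMatrix:
    """Build the Gram matrix R = Z Z^T of the expression rows.

    The rows are expected to be Z-scored already; with divisor m-ddof the
    diagonal entries then all equal m-ddof and R is (m-ddof) times the
    sample correlation matrix.

    Parameters
    ----------
    require_standardized
        When True (default), reject input whose row means exceed 1e-6 in
        magnitude — a sign the caller forgot to Z-score.
    """
    if X.n_genes < 2:
        raise ValueError("need at least two genes to form a Gram matrix")
    Z = X.values
    if require_standardized:
        worst = float(np.abs(Z.mean(axis=1)).max())
        if worst > 1e-6:
            raise ValueError(
                f"rows do not look Z-scored (max |row mean| = {worst:.3g}); "
                "standardize first or pass require_standardized=False"
            )
    R = Z @ Z.T
    R = (R + R.T) / 2.0  # enforce exact symmetry against rounding
    return GramMatrix(gene_ids=X.gene_ids, values=R, sample_count=X.n_samples)


def normalized_eigenvalues(R: GramMatrix | np.ndarray) -> EigenSpectrum:
    """Eigendecompose a symmetric PSD matrix and normalize the spectrum.

    Eigenvalues come from a symmetric eigensolver (so the eigenbasis is
    orthogonal and Q^{-1} = Q^T).  Tiny negative values down to
    -1e-8 x trace are clamped to zero; anything more negative is a genuine
    PSD violation and raises.  The clamped values are divided by their sum
    and returned in descending order.
    """
    if isinstance(R, GramMatrix):
        gene_ids, values = R.gene_ids, R.values
    else:
        values = np.asarray(R, dtype=float)
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("matrix is not symmetric within 1e-10")
        gene_ids = [f"g{i+1}" for i in range(values.shape[0])]

    eig = np.linalg.eigvalsh(values)
    trace = float(np.trace(values))
    tol = _PSD_RTOL * max(trace, 1.0)
    if eig.min() < -tol:
        raise np.linalg.LinAlgError(
            f"matrix is not PSD: eigenvalue {eig.min():.3g} below -{tol:.3g}"
        )
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    if total <= 0:
        raise ValueError("degenerate input: eigenvalue sum is not positive")
    lam = np.sort(eig / total)[::-1]
    return EigenSpectrum(values=lam, gene_ids=gene_ids)


def compare_spectra(
    spectrum_a: EigenSpectrum,
    spectrum_b: EigenSpectrum,
    group_a: str | None = None,
    group_b: str | None = None,
) -> SpectrumComparison:
    """Per-rank differences b - a between two spectra over the same genes."""
    return SpectrumComparison(
        group_a=group_a or spectrum_a.group or "a",
        group_b=group_b or spectrum_b.group or "b",
        spectrum_a=spectrum_a,
        spectrum_b=spectrum_b,
    )


def coordination_analysis(
    X: ExpressionMatrix,
    gene_set: list[str],
    anchor_gene: str | None = None,
    baseline_group: str | None = None,
    case_group: str | None = None,
    ddof: int = 1,
    zscore_scope: str = "within_group",
) -> SpectrumComparison:
    """Full two-group coordination pipeline for one gene set.

    Selects ``gene_set`` (plus ``anchor_gene``, e.g. MAPT or APP, appended
    if not already present), splits samples by group, Z-scores each gene
    within its group, builds the per-group Gram matrices and returns the
    comparison of their normalized spectra as case minus baseline.

    Parameters
    ----------
    baseline_group, case_group
        Which group plays control and which plays case.  If omitted the
        two group names are taken in sorted order (baseline first).
    zscore_scope
        ``"within_group"`` (default) standardizes each submatrix
        separately; ``"global"`` standardizes once across all samples
        before splitting — exposed because either reading is defensible
        for real data.
    """
    genes = list(gene_set)
    if anchor_gene is not None and anchor_gene not in genes:
        genes.append(anchor_gene)
    sub = select_genes(X, genes)
    if sub.groups is None:
        raise ValueError("group labels are required for coordination analysis")
    names = sub.group_names()
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, found {names}")
    if baseline_group is None and case_group is None:
        baseline_group, case_group = names
    elif baseline_group is None or case_group is None:
        known = set(names)
        given = baseline_group or case_group
        if given not in known:
            raise ValueError(f"unknown group {given!r}; groups are {names}")
        other = (known - {given}).pop()
        baseline_group = baseline_group or other
        case_group = case_group or other
    for g in (baseline_group, case_group):
        if g not in names:
            raise ValueError(f"unknown group {g!r}; groups are {names}")

    if zscore_scope == "global":
        sub = zscore_rows(sub, ddof=ddof)
    elif zscore_scope != "within_group":
        raise ValueError("zscore_scope must be 'within_group' or 'global'")

    spectra: dict[str, EigenSpectrum] = {}
    for name, part in split_by_group(sub).items():
        if zscore_scope == "within_group":
            part = zscore_rows(part, ddof=ddof)
        R = inner_product_matrix(part, require_standardized=(zscore_scope == "within_group"))
        s = normalized_eigenvalues(R)
        s.group = name
        spectra[name] = s

    return compare_spectra(
        spectra[baseline_group],
        spectra[case_group],
        group_a=baseline_group,
        group_b=case_group,
    )
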