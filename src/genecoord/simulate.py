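"""Synthetic two-group expression data with controlled coordination.

The generator draws log2-scale expression from a multivariate normal whose
correlation structure is block-diagonal: genes belonging to the same module
share a common pairwise (equi)correlation that may differ between the two
sample groups, genes in different modules are independent, and a subset of
genes may receive an additive mean shift in one group.  This is the minimal
generative model under which both the coordination statistic (group-specific
eigen-spectra) and the differential-expression / classification stages have
known ground truth:

* an n-gene module with equicorrelation rho has population normalized
  spectrum ((1+(n-1)rho)/n, (1-rho)/n, ...), so the spectrum a pipeline
  recovers can be checked against a closed form;
* a gene shifted by delta in one group has population logFC exactly delta.

``sample_from_correlation`` additionally accepts an arbitrary per-group
correlation matrix, so study designs whose spectra are *not* equicorrelated
(e.g. largest and smallest eigenvalue both larger in cases) can be emulated
by building a correlation matrix with a prescribed spectrum.

A companion generator plants hub nodes of exact degree in a random PPI-like
edge list, giving the degree-ranking stage a graph with known answers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "build_equicorrelation_matrix",
    "generate_dataset",
    "sample_from_correlation",
    "generate_edge_list",
    "write_edge_list",
]


def build_equicorrelation_matrix(n: int, rho: float) -> np.ndarray:
    """Correlation matrix with unit diagonal and constant off-diagonal rho.

    Positive semi-definite iff rho >= -1/(n-1); eigenvalues are
    1+(n-1)rho (once) and 1-rho (n-1 times).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 1 and not (-1.0 / (n - 1) < rho <= 1.0):
        raise ValueError(
            f"rho={rho} outside PSD range (-1/{n-1}, 1] for a {n}-gene block"
        )
    C = np.full((n, n), float(rho))
    np.fill_diagonal(C, 1.0)
    return C


@dataclass(frozen=True)
class SyntheticConfig:
    """Design of a two-group block-correlated expression study.

    Attributes
    ----------
    gene_modules
        Ordered (module_id, gene_ids) pairs; modules are disjoint.
    rho_per_group
        group -> module_id -> equicorrelation; unlisted modules default
        to 0 (independence) in that group.
    mean_shift
        gene -> additive shift (log2 units) applied in ``shift_group``.
    shift_group
        Group receiving the mean shifts; defaults to the first group of
        ``group_sizes`` in sorted order.
    group_sizes
        group -> sample count (each >= 2).
    noise_sd
        Per-gene standard deviation scaling the unit-variance blocks.
    background_genes
        Extra mutually independent genes outside any module.
    seed
        Single global seed; per-group substreams are derived from it.
    """

    gene_modules: tuple[tuple[str, tuple[str, ...]], ...]
    rho_per_group: dict[str, dict[str, float]]
    group_sizes: dict[str, int]
    mean_shift: dict[str, float] = field(default_factory=dict)
    shift_group: str | None = None
    noise_sd: float = 1.0
    background_genes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.group_sizes) < 1:
            raise ValueError("at least one group is required")
        for g, m in self.group_sizes.items():
            if m < 2:
                raise ValueError(f"group {g!r} has {m} samples; need >= 2")
        all_genes = self.gene_ids()
        if len(all_genes) != len(set(all_genes)):
            raise ValueError("gene IDs overlap across modules/background")
        module_ids = [mid for mid, _ in self.gene_modules]
        if len(module_ids) != len(set(module_ids)):
            raise ValueError("duplicate module IDs")
        sizes = {mid: len(genes) for mid, genes in self.gene_modules}
        for group, per_mod in self.rho_per_group.items():
            if group not in self.group_sizes:
                raise ValueError(f"rho given for unknown group {group!r}")
            for mid, rho in per_mod.items():
                if mid not in sizes:
                    raise ValueError(f"rho given for unknown module {mid!r}")
                build_equicorrelation_matrix(sizes[mid], rho)  # PSD check
        shift_group = self.resolved_shift_group()
        if self.mean_shift and shift_group not in self.group_sizes:
            raise ValueError(f"shift_group {shift_group!r} not in group_sizes")
        unknown = [g for g in self.mean_shift if g not in set(all_genes)]
        if unknown:
            raise ValueError(f"mean_shift refers to unknown gene(s): {unknown}")

    def gene_ids(self) -> list[str]:
        genes = [g for _, members in self.gene_modules for g in members]
        genes.extend(self.background_genes)
        return genes

    def resolved_shift_group(self) -> str:
        if self.shift_group is not None:
            return self.shift_group
        return sorted(self.group_sizes)[0]

    def correlation_for_group(self, group: str) -> np.ndarray:
        """Block-diagonal population correlation matrix for one group."""
        blocks = []
        per_mod = self.rho_per_group.get(group, {})
        for mid, members in self.gene_modules:
            blocks.append(build_equicorrelation_matrix(len(members), per_mod.get(mid, 0.0)))
        if self.background_genes:
            blocks.append(np.eye(len(self.background_genes)))
        if not blocks:
            raise ValueError("config defines no genes")
        n = sum(b.shape[0] for b in blocks)
        C = np.zeros((n, n))
        at = 0
        for b in blocks:
            k = b.shape[0]
            C[at : at + k, at : at + k] = b
            at += k
        return C


def _group_rng(seed: int, group_index: int) -> np.random.Generator:
    # deterministic substream per group from the single global seed
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(group_index,)))


def _sample_group(
    rng: np.random.Generator,
    corr: np.ndarray,
    mean: np.ndarray,
    sd: float,
    m: int,
) -> np.ndarray:
    cov = (sd * sd) * corr
    draws = rng.multivariate_normal(mean, cov, size=m, method="eigh")
    return draws.T  # genes x samples


def generate_dataset(config: SyntheticConfig) -> ExpressionMatrix:
    """Draw a labelled genes x samples matrix from the configured design.

    Reproducible bit-for-bit from ``config.seed``; sample IDs are
    ``<group>_<i>`` and carry their group label.
    """
    genes = config.gene_ids()
    shift_group = config.resolved_shift_group()
    shift = np.array([config.mean_shift.get(g, 0.0) for g in genes])

    columns: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for gi, group in enumerate(sorted(config.group_sizes)):
        m = config.group_sizes[group]
        corr = config.correlation_for_group(group)
        mean = shift if group == shift_group else np.zeros(len(genes))
        rng = _group_rng(config.seed, gi)
        blocks.append(_sample_group(rng, corr, mean, config.noise_sd, m))
        columns.extend(f"{group}_{i+1}" for i in range(m))
        labels.extend([group] * m)

    data = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    groups = pd.Series(labels, index=columns, name="group")
    return ExpressionMatrix(data=data, groups=groups)


def sample_from_correlation(
    correlation_per_group: dict[str, np.ndarray],
    group_sizes: dict[str, int],
    gene_ids: list[str],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Draw a two-group dataset from explicit per-group correlation matrices.

    Complements :func:`generate_dataset` for designs beyond equicorrelated
    blocks — e.g. a correlation matrix constructed to have a prescribed
    eigen-spectrum.  Matrices must be symmetric PSD with unit diagonal.
    """
    columns: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for gi, group in enumerate(sorted(group_sizes)):
        corr = np.asarray(correlation_per_group[group], dtype=float)
        if corr.shape != (len(gene_ids), len(gene_ids)):
            raise ValueError(f"correlation for {group!r} has wrong shape {corr.shape}")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
            raise ValueError(f"correlation for {group!r} lacks a unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8 * len(gene_ids):
            raise ValueError(f"correlation for {group!r} is not PSD")
        m = group_sizes[group]
        rng = _group_rng(seed, gi)
        blocks.append(_sample_group(rng, corr, np.zeros(len(gene_ids)), noise_sd, m))
        columns.extend(f"{group}_{i+1}" for i in range(m))
        labels.extend([group] * m)
    data = pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=columns)
    return ExpressionMatrix(data=data, groups=pd.Series(labels, index=columns, name="group"))


# ---------------------------------------------------------------------------
# PPI-like edge lists with planted hubs
# ---------------------------------------------------------------------------


def generate_edge_list(
    n_nodes: int,
    planted_hubs: list[tuple[str, int]],
    seed: int = 0,
    background_prob: float = 0.05,
) -> nx.Graph:
    """Random undirected graph in which named hubs have exact degrees.

    Every planted hub ends with exactly its requested degree and every
    other node with a strictly smaller degree, so a degree ranking has a
    known answer.  Each edge carries a uniform confidence score in
    [0.5, 1.0] under the attribute ``"score"``.

    Raises
    ------
    ValueError
        If a requested degree is infeasible (>= n_nodes, or cannot be met
        while keeping non-hub degrees strictly smaller).
    """
    rng = np.random.default_rng(seed)
    hub_names = [name for name, _ in planted_hubs]
    if len(hub_names) != len(set(hub_names)):
        raise ValueError("duplicate hub names")
    for name, deg in planted_hubs:
        if deg < 1 or deg >= n_nodes:
            raise ValueError(f"hub {name!r} requests degree {deg}, needs 1 <= d < {n_nodes}")
    n_fillers = n_nodes - len(hub_names)
    if n_fillers < 0:
        raise ValueError("more hubs than nodes")
    fillers = [f"N{i+1:03d}" for i in range(n_fillers)]

    G: nx.Graph = nx.Graph()
    G.add_nodes_from(hub_names)
    G.add_nodes_from(fillers)

    hubs_desc = sorted(planted_hubs, key=lambda t: (-t[1], t[0]))
    remaining = {name: deg for name, deg in hubs_desc}
    for name, deg in hubs_desc:
        need = remaining[name]
        if need <= 0:
            continue
        # prefer lowest-degree fillers; fall back to other needy hubs
        pool = sorted(fillers, key=lambda f: (G.degree(f), f))
        chosen = [f for f in pool if not G.has_edge(name, f)][:need]
        if len(chosen) < need:
            needy = [
                h for h, _ in hubs_desc
                if h != name and remaining[h] > 0 and not G.has_edge(name, h)
            ]
            extra = needy[: need - len(chosen)]
            for h in extra:
                remaining[h] -= 1
            chosen.extend(extra)
        if len(chosen) < need:
            raise ValueError(f"cannot satisfy degree {deg} for hub {name!r}")
        G.add_edges_from((name, other) for other in chosen)
        remaining[name] = 0

    # background edges among fillers, kept strictly below the hub degrees
    min_hub_deg = min((d for _, d in planted_hubs), default=n_nodes - 1)
    cap = min_hub_deg - 1 if planted_hubs else n_nodes - 2
    for u, v in itertools.combinations(fillers, 2):
        if G.degree(u) < cap and G.degree(v) < cap and rng.random() < background_prob:
            G.add_edge(u, v)

    for name, deg in planted_hubs:
        if G.degree(name) != deg:
            raise ValueError(f"hub {name!r} ended with degree {G.degree(name)} != {deg}")
    worst = max((G.degree(f) for f in fillers), default=0)
    if planted_hubs and worst >= min_hub_deg:
        raise ValueError("a non-hub node reached hub degree; lower background_prob")

    for u, v in G.edges:
        G.edges[u, v]["score"] = float(rng.uniform(0.5, 1.0))
    return G


def write_edge_list(G: nx.Graph, path) -> None:
    """Write a 3-column TSV (node_a, node_b, score) edge list."""
    rows = [
        {"node_a": u, "node_b": v, "score": round(d.get("score", 1.0), 6)}
        for u, v, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "score"]).to_csv(
        path, sep="\t", index=False
    )
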