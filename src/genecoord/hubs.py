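"""PPI edge-list ingestion, confidence filtering and degree-based hub ranking.

Mirrors the usual STRING-export workflow: keep edges at or above a minimum
interaction score (0.99 for a high-confidence network), hide disconnected
nodes, rank the remainder by plain degree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

__all__ = ["HubRanking", "read_edge_list", "drop_isolated_nodes", "degree_ranking"]

_HEADER_HINTS = {"node_a", "node_b", "nodea", "nodeb", "protein1", "protein2", "score"}


@dataclass
class HubRanking:
    """Top-k nodes by degree; ties broken by node ID."""

    ranked: list[tuple[str, int]]
    k: int

    @property
    def nodes(self) -> list[str]:
        return [n for n, _ in self.ranked]


def read_edge_list(path: str | Path, min_score: float = 0.0) -> nx.Graph:
    """Parse a 2- or 3-column TSV edge list into an undirected simple graph.

    Self-loops and duplicate (unordered) edges are dropped.  When a score
    column is present, edges scoring below ``min_score`` are removed;
    STRING's 0-1000 integer dialect is auto-detected (any score > 1 means
    the whole column is divided by 1000).
    """
    raw: list[tuple[str, str, float | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            a, b = parts[0].strip(), parts[1].strip()
            score: float | None = None
            if len(parts) >= 3 and parts[2].strip() != "":
                try:
                    score = float(parts[2])
                except ValueError:
                    if lineno == 1 and a.lower() in _HEADER_HINTS:
                        continue  # header row
                    raise ValueError(f"{path}:{lineno}: malformed score {parts[2]!r}") from None
            elif lineno == 1 and a.lower() in _HEADER_HINTS:
                continue
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty node ID")
            raw.append((a, b, score))

    scores = [s for _, _, s in raw if s is not None]
    scale = 1000.0 if scores and max(scores) > 1.0 else 1.0
    G: nx.Graph = nx.Graph()
    for a, b, s in raw:
        if a == b:
            continue
        if s is not None:
            s = s / scale
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"score {s} outside [0, 1] for edge ({a}, {b})")
            if s < min_score:
                continue
            G.add_edge(a, b, score=s)
        else:
            G.add_edge(a, b)
    return G


def drop_isolated_nodes(G: nx.Graph, node_universe: list[str] | None = None) -> list[str]:
    """Nodes incident to at least one retained edge, sorted.

    ``node_universe`` optionally restricts candidates (e.g. the full DEG
    list, most of which never made it into an edge).
    """
    connected = {n for n in G.nodes if G.degree(n) > 0}
    if node_universe is not None:
        connected &= set(node_universe)
    return sorted(connected)


def degree_ranking(G: nx.Graph, k: int) -> HubRanking:
    """Top-k nodes by unweighted degree, ties by lexicographic node ID."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(((n, G.degree(n)) for n in G.nodes), key=lambda t: (-t[1], t[0]))
    return HubRanking(ranked=ranked[:k], k=k)
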