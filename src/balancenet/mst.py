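"""Spanning-tree backbone of a connectivity matrix and integration metrics.

The "minimum spanning tree" of a synchrony matrix follows the field
convention: the spanning tree retaining the *strongest* connections
(equivalently the minimum spanning tree of distance ``1 - w``). Four
topology-only measures summarize how integrated (star-like) versus
dispersed (path-like) the backbone is:

diameter
    longest path in the tree, in edges, normalized by M = N - 1.
leaf fraction
    number of degree-1 nodes over the maximum possible (N - 1, a star).
average eccentricity
    mean over nodes of the longest distance to any other node, / (N - 1).
BC_max
    largest betweenness centrality, i.e. the greatest share of the
    (N-1)(N-2)/2 shortest paths routed through a single node.

Higher leaf fraction and BC_max with lower diameter and eccentricity mark
a more integrated network. All normalizations land the metrics in [0, 1]
and can be disabled with ``normalize=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix
from .core import DataError

__all__ = [
    "SpanningTree",
    "TreeMetrics",
    "max_spanning_tree",
    "tree_diameter",
    "leaf_fraction",
    "avg_eccentricity",
    "bc_max",
    "tree_metrics",
    "aggregate_metrics",
]


@dataclass
class SpanningTree:
    """A spanning tree as N-1 weighted edges over labeled nodes."""

    n_nodes: int
    edges: list[tuple[int, int, float]]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise DataError(
                f"a spanning tree on {self.n_nodes} nodes needs "
                f"{self.n_nodes - 1} edges, got {len(self.edges)}"
            )

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def max_spanning_tree(cm: ConnectivityMatrix | np.ndarray) -> SpanningTree:
    """Maximum-weight spanning tree by Kruskal on descending weight.

    Ties are broken by lexicographic (i, j) edge order, so the tree is
    deterministic even on degenerate (all-equal) matrices. NaN entries
    (pairs involving a flagged channel) are treated as weight 0. If the
    positive-weight subgraph is disconnected the zero edges still allow a
    spanning tree; a warning is emitted since the "backbone" reading is
    then weak.
    """
    if isinstance(cm, ConnectivityMatrix):
        w, labels = cm.w, cm.labels
    else:
        w = np.asarray(cm, dtype=float)
        labels = ()
    n = w.shape[0]
    if n < 2:
        raise DataError("need at least 2 nodes for a spanning tree")
    if w.shape != (n, n):
        raise DataError("weight matrix must be square")
    wc = np.where(np.isnan(w), 0.0, w)
    if np.any(wc < 0):
        raise DataError("connectivity weights must be non-negative")
    edges = [(i, j, float(wc[i, j])) for i in range(n) for j in range(i + 1, n)]
    # descending weight, then lexicographic (i, j); exact float comparison
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    uf = _UnionFind(n)
    chosen: list[tuple[int, int, float]] = []
    used_zero = False
    for i, j, wt in edges:
        if uf.union(i, j):
            chosen.append((i, j, wt))
            used_zero = used_zero or wt == 0.0
            if len(chosen) == n - 1:
                break
    if used_zero:
        import warnings

        warnings.warn(
            "spanning tree includes zero-weight edges; the positive-weight "
            "graph is disconnected", stacklevel=2,
        )
    return SpanningTree(n, chosen, labels)


def _as_graph(t: SpanningTree) -> nx.Graph:
    return t.to_networkx()


def tree_diameter(t: SpanningTree, normalize: bool = True) -> float:
    """Longest shortest path in edges, / (N - 1) if normalized."""
    d = nx.diameter(_as_graph(t))
    return d / (t.n_nodes - 1) if normalize else float(d)


def leaf_fraction(t: SpanningTree) -> float:
    """Degree-1 node count over the star maximum N - 1."""
    g = _as_graph(t)
    leaves = sum(1 for _, deg in g.degree if deg == 1)
    return leaves / (t.n_nodes - 1)


def avg_eccentricity(t: SpanningTree, normalize: bool = True) -> float:
    """Mean node eccentricity in edges, / (N - 1) if normalized."""
    ecc = nx.eccentricity(_as_graph(t))
    m = float(np.mean(list(ecc.values())))
    return m / (t.n_nodes - 1) if normalize else m


def bc_max(t: SpanningTree, normalize: bool = True) -> float:
    """Largest betweenness centrality over nodes.

    In a tree every node pair has a unique path; normalized betweenness is
    the fraction of the (N-1)(N-2)/2 pairs whose path crosses the node.
    """
    if t.n_nodes < 3:
        raise DataError("betweenness needs at least 3 nodes")
    bc = nx.betweenness_centrality(_as_graph(t), normalized=normalize)
    return float(max(bc.values()))


@dataclass(frozen=True)
class TreeMetrics:
    """The four integration measures of one (or an average of) tree(s)."""

    diameter: float
    leaf_fraction: float
    avg_eccentricity: float
    bc_max: float

    def as_dict(self) -> dict[str, float]:
        return {
            "diameter": self.diameter,
            "leaf_fraction": self.leaf_fraction,
            "avg_eccentricity": self.avg_eccentricity,
            "bc_max": self.bc_max,
        }


def tree_metrics(t: SpanningTree, normalize: bool = True) -> TreeMetrics:
    return TreeMetrics(
        diameter=tree_diameter(t, normalize),
        leaf_fraction=leaf_fraction(t),
        avg_eccentricity=avg_eccentricity(t, normalize),
        bc_max=bc_max(t, normalize),
    )


def aggregate_metrics(
    groups: Iterable[Sequence[TreeMetrics]] | Sequence[TreeMetrics],
) -> TreeMetrics:
    """Average tree metrics, epochs first, then across trials.

    Accepts either a flat sequence of per-epoch metrics (one trial) or an
    iterable of such sequences (one per trial). Each trial is averaged over
    its epochs before trials are averaged, so trials with unequal epoch
    counts carry equal weight — the pooled mean would not.
    """
    items = list(groups)
    if not items:
        raise DataError("no tree metrics to aggregate")
    if isinstance(items[0], TreeMetrics):
        trials = [items]  # single trial
    else:
        trials = [list(tr) for tr in items]
        if any(not tr for tr in trials):
            raise DataError("every trial must contribute at least one tree")
    per_trial = np.array(
        [
            np.mean([[m.diameter, m.leaf_fraction, m.avg_eccentricity, m.bc_max]
                     for m in tr], axis=0)
            for tr in trials
        ]
    )
    d, lf, ecc, bc = per_trial.mean(axis=0)
    return TreeMetrics(float(d), float(lf), float(ecc), float(bc))
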