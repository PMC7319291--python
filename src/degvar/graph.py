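"""Simple undirected graphs and weighted matrices.

The :class:`Graph` container is deliberately minimal: a node count and a
frozen set of unordered 0-based index pairs.  It enforces the simple-graph
invariants (no self-loops, no duplicates, indices in range) at construction
and is immutable — every operation that "changes" a graph returns a new one.
Degree and edge arrays are cached, so repeated metric evaluation on the same
graph costs one pass over the edges in total.

:class:`WeightedMatrix` carries a symmetric nonnegative weight matrix with a
zero diagonal, the input to density thresholding (binarisation): keep the m
largest-weight pairs where m = round(d * n(n-1)/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

Edge = tuple[int, int]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero.

    Python's built-in round() uses banker's rounding; edge/node counts
    derived from target densities and removal fractions use this convention
    instead so realised counts are closest to the target and deterministic.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _canon(i: int, j: int) -> Edge:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class Graph:
    """Immutable simple undirected graph on nodes 0..n-1."""

    n: int
    edges: frozenset[Edge]
    labels: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"node count must be positive, got {self.n}")
        if not isinstance(self.edges, frozenset):
            object.__setattr__(self, "edges", frozenset(self.edges))
        if self.edges:
            e = np.array(list(self.edges), dtype=np.int64)
            if np.any(e[:, 0] == e[:, 1]):
                raise ValueError("self-loops not allowed")
            if np.any(e[:, 0] > e[:, 1]):
                raise ValueError("edges must be canonical (i < j) pairs")
            if e.min() < 0 or e.max() >= self.n:
                raise ValueError("edge endpoint out of range")
            # lexicographically sorted edge array, cached for metric code
            order = np.lexsort((e[:, 1], e[:, 0]))
            object.__setattr__(self, "_earr", e[order])
        else:
            object.__setattr__(self, "_earr", np.empty((0, 2), dtype=np.int64))
        if self.labels is not None and len(self.labels) != self.n:
            raise ValueError("label table length must equal n")

    @classmethod
    def from_edges(
        cls,
        n: int,
        pairs: Iterable[tuple[int, int]],
        labels: Sequence[str] | None = None,
    ) -> "Graph":
        """Build from arbitrary (i, j) pairs, canonicalising order."""
        es = frozenset(_canon(i, j) for i, j in pairs)
        return cls(n, es, tuple(labels) if labels is not None else None)

    @classmethod
    def from_networkx(cls, g) -> "Graph":
        nodes = sorted(g.nodes())
        idx = {u: i for i, u in enumerate(nodes)}
        pairs = (_canon(idx[u], idx[v]) for u, v in g.edges() if u != v)
        return cls(len(nodes), frozenset(pairs), tuple(str(u) for u in nodes))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    @property
    def m(self) -> int:
        """Number of edges."""
        return len(self.edges)

    @property
    def max_edges(self) -> int:
        return self.n * (self.n - 1) // 2

    def degree_array(self) -> np.ndarray:
        """Degrees k_i as an int array (cached)."""
        cached = getattr(self, "_degrees", None)
        if cached is None:
            cached = np.bincount(self._earr.ravel(), minlength=self.n)
            object.__setattr__(self, "_degrees", cached)
        return cached

    def edge_array(self) -> np.ndarray:
        """(m, 2) int array of edges, lexicographically sorted."""
        return self._earr


def degree_sequence(g: Graph) -> list[int]:
    """Degrees k_i of every node; sums to 2m."""
    return g.degree_array().tolist()


def density(g: Graph) -> float:
    """Fraction of possible edges present, d = 2m / n(n-1)."""
    if g.n < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2 * g.m / (g.n * (g.n - 1))


def _encode(e: np.ndarray, n: int) -> np.ndarray:
    return e[:, 0] * n + e[:, 1]


def complement(g: Graph) -> Graph:
    """Graph with an edge exactly where ``g`` has none.

    Degrees satisfy k̂_i = n - 1 - k_i and m̂ = n(n-1)/2 - m.
    """
    n = g.n
    iu, ju = np.triu_indices(n, k=1)
    all_ids = iu * n + ju
    present = _encode(g.edge_array(), n)
    comp_ids = np.setdiff1d(all_ids, present, assume_unique=True)
    ci, cj = comp_ids // n, comp_ids % n
    return Graph(n, frozenset(zip(ci.tolist(), cj.tolist())), g.labels)


@dataclass(frozen=True)
class WeightedMatrix:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T, atol=1e-9, rtol=0.0):
            raise ValueError("weight matrix must be symmetric (within 1e-9)")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n(self) -> int:
        return self.w.shape[0]


def threshold_to_density(wm: WeightedMatrix, d: float) -> Graph:
    """Binarise a weighted matrix at a target density.

    Keeps the m = round(d * n(n-1)/2) largest-weight node pairs as edges.
    Ties are broken by lexicographic pair order so the output is
    deterministic, and outputs at increasing d are nested.
    """
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"density must be in [0,1], got {d}")
    n = wm.n
    iu, ju = np.triu_indices(n, k=1)
    weights = wm.w[iu, ju]
    m = round_half_away(d * n * (n - 1) / 2)
    # stable sort on lexicographic pairs, then stable sort by descending
    # weight: equal weights keep lexicographic order
    order = np.argsort(-weights, kind="stable")
    keep = order[:m]
    return Graph(n, frozenset(zip(iu[keep].tolist(), ju[keep].tolist())))
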