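"""Extremal graph constructors and seeded random ensembles.

Quasi-star and quasi-complete graphs are the extremal families for degree
variance at fixed (n, m): among all simple graphs with n nodes and m edges,
the maximum degree variance is attained by one of the two (Bell's theorem).

A quasi-complete graph is a clique of the largest order s with s(s-1)/2 <= m,
one further node attached to r = m - s(s-1)/2 clique members, and isolated
remainder nodes.  The quasi-star graph is its complement family: r dominant
nodes (degree n-1) plus a small remainder structure.  The verbal edge-count
descriptions of quasi-stars in the literature are ambiguous; the complement
construction is not, and reproduces the perfect-graph duality (the perfect
quasi-complete graph of order r is the complement of the perfect quasi-star
of order n-r), so ``quasi_star(n, m)`` is defined as
``complement(quasi_complete(n, n(n-1)/2 - m))``.

Random ensembles (all bit-reproducible under a fixed seed):

* ``er_gnm`` / ``er_gnp`` — the two Erdős–Rényi ensembles.
* ``weighted_er`` — i.i.d. uniform symmetric weight matrices; thresholding
  one at density d yields a G(n, m) draw.
* ``random_geometric_weighted`` — weights decreasing in Euclidean distance
  between points uniform in the unit square, so thresholded graphs are
  random geometric graphs.
* ``scale_free_core`` — a complete core plus linear preferential attachment
  without replacement, giving heavy-tailed degrees at a prescribed density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np

from .graph import Graph, WeightedMatrix, complement, round_half_away

__all__ = [
    "QuasiGraphSpec",
    "GeneratorSpec",
    "quasi_complete",
    "quasi_star",
    "perfect_quasistar_densities",
    "er_gnm",
    "er_gnp",
    "weighted_er",
    "random_geometric_weighted",
    "scale_free_core",
    "star_graph",
    "cycle_graph",
    "complete_graph",
    "path_graph",
    "circulant_graph",
    "empty_graph",
]


@dataclass(frozen=True)
class QuasiGraphSpec:
    """(n, r, s) decomposition of a quasi-star or quasi-complete graph."""

    n: int
    r: int
    s: int


def quasi_complete(n: int, m: int) -> Graph:
    """Quasi-complete graph: s-clique + one node attached to r clique members.

    s is the largest clique order with s(s-1)/2 <= m and r = m - s(s-1)/2;
    all other nodes are isolated.  Exactly m edges.
    """
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"m must be in [0, {max_m}], got {m}")
    s = 1
    while (s + 1) * s // 2 <= m:
        s += 1
    r = m - s * (s - 1) // 2
    edges = [(i, j) for i in range(s) for j in range(i + 1, s)]
    if r > 0:
        edges.extend((i, s) for i in range(r))
    return Graph.from_edges(n, edges)


def quasi_star(n: int, m: int) -> Graph:
    """Quasi-star graph: r dominant nodes plus at most one developing node.

    Defined as the complement of ``quasi_complete(n, n(n-1)/2 - m)``, which
    guarantees exactly m edges and the dominant-node structure.
    """
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"m must be in [0, {max_m}], got {m}")
    return complement(quasi_complete(n, max_m - m))


def quasi_spec(n: int, m: int) -> QuasiGraphSpec:
    """(n, r, s) parameters of the quasi-complete decomposition of m."""
    s = 1
    while (s + 1) * s // 2 <= m:
        s += 1
    return QuasiGraphSpec(n, m - s * (s - 1) // 2, s)


def perfect_quasistar_densities(n: int) -> list[tuple[int, int, float]]:
    """(r, m, d) for every perfect quasi-star with integer edge count.

    A perfect quasi-star with r dominant nodes has 2m = r(2n-r-1); values
    of r yielding half-integer m are skipped.
    """
    if n < 2:
        raise ValueError("requires n >= 2")
    out = []
    for r in range(1, n):
        twice_m = r * (2 * n - r - 1)
        if twice_m % 2 == 0:
            m = twice_m // 2
            out.append((r, m, 2 * m / (n * (n - 1))))
    return out


# ---------------------------------------------------------------------------
# random ensembles


def er_gnm(n: int, m: int, seed: int | np.random.Generator) -> Graph:
    """Uniform draw over simple graphs with exactly n nodes and m edges."""
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"m must be in [0, {max_m}], got {m}")
    rng = np.random.default_rng(seed)
    # sample m distinct pair indices uniformly, decode to (i, j)
    idx = rng.choice(max_m, size=m, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    return Graph(n, frozenset(zip(iu[idx].tolist(), ju[idx].tolist())))


def er_gnp(n: int, p: float, seed: int | np.random.Generator) -> Graph:
    """Each of the n(n-1)/2 pairs is an edge independently with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    return Graph(n, frozenset(zip(iu[keep].tolist(), ju[keep].tolist())))


def weighted_er(n: int, seed: int | np.random.Generator) -> WeightedMatrix:
    """Symmetric matrix of i.i.d. uniform(0,1) off-diagonal weights."""
    if n < 2:
        raise ValueError("requires n >= 2")
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    vals = rng.random(iu.size)
    w[iu, ju] = vals
    w[ju, iu] = vals
    return WeightedMatrix(w)


def random_geometric_weighted(n: int, seed: int | np.random.Generator) -> WeightedMatrix:
    """Geometric weights: 1 - (Euclidean distance / sqrt(2)) between points
    uniform in the unit square, so nearby pairs carry the largest weights.

    Any strictly decreasing function of distance yields the same thresholded
    graphs; this one keeps weights in [0, 1].
    """
    if n < 2:
        raise ValueError("requires n >= 2")
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 2))
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    w = 1.0 - dist / np.sqrt(2.0)
    np.fill_diagonal(w, 0.0)
    return WeightedMatrix(w)


def scale_free_core(
    n: int,
    core_frac: float,
    attach_frac: float,
    seed: int | np.random.Generator,
) -> Graph:
    """Complete core + linear preferential attachment, fixed edge budget.

    round(core_frac * n) nodes form a clique; every remaining node attaches
    round(attach_frac * n) edges to distinct existing nodes chosen with
    probability proportional to current degree (no replacement).  Total
    edge count is the deterministic C(c,2) + (n-c)*a.
    """
    if not (0 < core_frac < 1 and 0 < attach_frac < 1):
        raise ValueError("core_frac and attach_frac must be in (0,1)")
    c = round_half_away(core_frac * n)
    a = round_half_away(attach_frac * n)
    if a > c:
        raise ValueError(
            f"attachment count {a} exceeds initial core size {c}"
        )
    if c < 2:
        raise ValueError("core must have at least 2 nodes")
    rng = np.random.default_rng(seed)
    deg = np.zeros(n, dtype=np.int64)
    deg[:c] = c - 1
    edges = [(i, j) for i in range(c) for j in range(i + 1, c)]
    for v in range(c, n):
        weights = deg[:v].astype(float)
        targets = rng.choice(v, size=a, replace=False, p=weights / weights.sum())
        for t in targets.tolist():
            edges.append((t, v) if t < v else (v, t))
            deg[t] += 1
        deg[v] = a
    return Graph.from_edges(n, edges)


# ---------------------------------------------------------------------------
# deterministic convenience constructors


def star_graph(n: int) -> Graph:
    """Hub node 0 joined to the n-1 others."""
    return Graph.from_edges(n, ((0, i) for i in range(1, n)))


def cycle_graph(n: int) -> Graph:
    return Graph.from_edges(n, ((i, (i + 1) % n) for i in range(n)))


def complete_graph(n: int) -> Graph:
    return Graph.from_edges(
        n, ((i, j) for i in range(n) for j in range(i + 1, n))
    )


def path_graph(n: int) -> Graph:
    return Graph.from_edges(n, ((i, i + 1) for i in range(n - 1)))


def circulant_graph(n: int, offsets: tuple[int, ...] = (1, 2)) -> Graph:
    """Circulant (regular) graph; default offsets (1, 2) give a 4-regular one."""
    return Graph.from_networkx(nx.circulant_graph(n, list(offsets)))


def empty_graph(n: int) -> Graph:
    return Graph(n, frozenset())


# ---------------------------------------------------------------------------
# uniform generator dispatch, used by the sweep harness and the CLI


@dataclass(frozen=True)
class GeneratorSpec:
    """Family name + parameters + seed; the seed fully determines output."""

    family: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


# weighted families produce a WeightedMatrix to be thresholded at a target
# density; graph families take the density/edge count directly.
WEIGHTED_FAMILIES = {"weighted_er", "random_geometric"}


def build_graph(family: str, n: int, m: int, rng: np.random.Generator,
                **params) -> Graph:
    """Construct one graph of the given family with n nodes and m edges.

    For weighted families the matrix is drawn and thresholded to the density
    2m/(n(n-1)); scale-free ignores m (its edge count is fixed by its
    fractions).
    """
    from .graph import threshold_to_density

    d = 2 * m / (n * (n - 1))
    if family == "quasi_star":
        return quasi_star(n, m)
    if family == "quasi_complete":
        return quasi_complete(n, m)
    if family == "er_gnm":
        return er_gnm(n, m, rng)
    if family == "er_gnp":
        return er_gnp(n, params.get("p", d), rng)
    if family == "weighted_er":
        return threshold_to_density(weighted_er(n, rng), d)
    if family == "random_geometric":
        return threshold_to_density(random_geometric_weighted(n, rng), d)
    if family == "scale_free_core":
        return scale_free_core(
            n,
            params.get("core_frac", 0.125),
            params.get("attach_frac", 0.0625),
            rng,
        )
    if family in _PLUGINS:
        return _PLUGINS[family](n=n, m=m, rng=rng, **params)
    raise ValueError(f"unknown generator family {family!r}")


def random_graph_suite(
    count: int,
    seed: int,
    families: tuple[str, ...] = (
        "quasi_star",
        "quasi_complete",
        "er_gnm",
        "random_geometric",
        "scale_free_core",
    ),
    n_min: int = 4,
    n_max: int = 256,
):
    """Yield ``count`` seeded graphs cycling through the listed families.

    Sizes are drawn uniformly from [n_min, n_max] and densities uniformly
    from (0, 1) with edge counts clipped to the non-trivial range
    [1, n(n-1)/2 - 1].  Scale-free graphs need a core of at least 2 nodes
    and one attachment edge, so their sizes are drawn from [max(16, n_min),
    n_max].  Used as the randomized property-test suite spanning every
    generator family.
    """
    rng = np.random.default_rng(seed)
    for i in range(count):
        family = families[i % len(families)]
        lo = max(16, n_min) if family == "scale_free_core" else n_min
        n = int(rng.integers(lo, n_max + 1))
        max_m = n * (n - 1) // 2
        m = int(np.clip(round_half_away(rng.random() * max_m), 1, max_m - 1))
        yield build_graph(family, n, m, rng)


_PLUGINS: dict[str, Callable[..., Graph]] = {}


def register_family(name: str, fn: Callable[..., Graph]) -> None:
    """Register a user-supplied generator (e.g. a hierarchy model) so the
    sweep harness can drive it alongside the built-in families."""
    _PLUGINS[name] = fn
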