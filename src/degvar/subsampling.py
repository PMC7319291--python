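"""Node and edge subsampling for robustness analysis.

Three removal schemes are provided:

* nodes uniformly at random (induced subgraph on the survivors);
* edges uniformly at random;
* edges with probability inversely related to the degrees of their
  endpoints, p ∝ h_ij = ((n-1)-k_i)((n-1)-k_j) — removal preferentially
  targets edges between low-degree nodes, better retaining the network's
  expected topology.

In the inverse-degree scheme h_ij is computed once from the original
degrees; edges are then drawn sequentially without replacement by
inverse-transform sampling on the cumulative h vector, renormalising over
the surviving edges after each draw.  If every h_ij is zero (e.g. a star or
a complete graph, where every edge touches a dominant node) the scheme
degenerates and uniform removal is used instead, with a logged warning.

Counts removed are round(fraction * count), halves away from zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import Graph, round_half_away
from .metrics import (
    heterogeneity_index,
    normalized_degree_variance,
)
from .undefined import Undefined, is_defined

logger = logging.getLogger(__name__)

__all__ = [
    "RemovalPlan",
    "remove_nodes_uniform",
    "remove_edges_uniform",
    "remove_edges_inverse_degree",
    "robustness_profile",
]

MODES = ("nodes_uniform", "edges_uniform", "edges_inverse_degree")


@dataclass(frozen=True)
class RemovalPlan:
    mode: str
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0,1]")


def _check_fraction(fraction: float) -> None:
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")


def remove_nodes_uniform(
    g: Graph, fraction: float, seed: int | np.random.Generator
) -> Graph:
    """Induced subgraph on n - round(fraction*n) uniformly chosen nodes."""
    _check_fraction(fraction)
    n_remove = round_half_away(fraction * g.n)
    if n_remove >= g.n:
        raise ValueError("cannot remove all nodes")
    if n_remove == 0:
        return g
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(g.n, size=g.n - n_remove, replace=False))
    relabel = {old: new for new, old in enumerate(keep.tolist())}
    edges = [
        (relabel[i], relabel[j])
        for i, j in g.edges
        if i in relabel and j in relabel
    ]
    return Graph.from_edges(len(keep), edges)


def remove_edges_uniform(
    g: Graph, fraction: float, seed: int | np.random.Generator
) -> Graph:
    """Remove round(fraction*m) edges uniformly without replacement."""
    _check_fraction(fraction)
    n_remove = round_half_away(fraction * g.m)
    if n_remove == 0:
        return g
    rng = np.random.default_rng(seed)
    edges = sorted(g.edges)
    drop = set(rng.choice(g.m, size=n_remove, replace=False).tolist())
    return Graph(g.n, frozenset(e for i, e in enumerate(edges) if i not in drop))


def remove_edges_inverse_degree(
    g: Graph, fraction: float, seed: int | np.random.Generator
) -> Graph:
    """Remove edges with probability proportional to h_ij (inverse degree).

    h_ij = ((n-1)-k_i)((n-1)-k_j) is frozen at the original degrees; draws
    are sequential without replacement, renormalising over survivors.
    """
    _check_fraction(fraction)
    n_remove = round_half_away(fraction * g.m)
    if n_remove == 0:
        return g
    rng = np.random.default_rng(seed)
    edges = g.edge_array()
    k = g.degree_array()
    h = ((g.n - 1) - k[edges[:, 0]]) * ((g.n - 1) - k[edges[:, 1]])
    h = h.astype(float)
    if h.sum() == 0.0:
        logger.warning(
            "all inverse-degree weights are zero (every edge touches a "
            "dominant node); falling back to uniform edge removal"
        )
        return remove_edges_uniform(g, fraction, rng)
    alive = np.ones(g.m, dtype=bool)
    for _ in range(n_remove):
        w = h * alive
        total = w.sum()
        if total == 0.0:  # surviving edges all have zero weight
            idx_alive = np.flatnonzero(alive)
            pick = idx_alive[rng.integers(idx_alive.size)]
        else:
            cum = np.cumsum(w) / total
            pick = int(np.searchsorted(cum, rng.random(), side="right"))
        alive[pick] = False
    kept = edges[alive]
    return Graph(g.n, frozenset(map(tuple, kept.tolist())))


def _rho_safe(g: Graph):
    # subsamples of tiny graphs can drop below rho's n >= 3 domain
    return heterogeneity_index(g) if g.n >= 3 else Undefined("n_below_3")


_METRICS = {
    "vbar": normalized_degree_variance,
    "rho": _rho_safe,
}


def robustness_profile(
    g: Graph,
    fractions: list[float],
    reps: int,
    seed: int,
    metrics: tuple[str, ...] = ("vbar", "rho"),
    modes: tuple[str, ...] = MODES,
) -> pd.DataFrame:
    """Mean metric shift under repeated subsampling.

    For every (mode, fraction) pair, ``reps`` independent subsamples are
    drawn and each metric is averaged over the repetitions where it was
    defined (rho fails whenever a subsample contains an isolated node; such
    repetitions are counted, not averaged).  Columns: mode, fraction,
    metric, value (original), mean_sub, abs_diff, undefined_frac,
    edge_loss_frac (node mode only, NaN otherwise).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    removers = {
        "nodes_uniform": remove_nodes_uniform,
        "edges_uniform": remove_edges_uniform,
        "edges_inverse_degree": remove_edges_inverse_degree,
    }
    base = {name: _METRICS[name](g) for name in metrics}
    rows = []
    for mode in modes:
        fn = removers[mode]
        for frac in fractions:
            vals: dict[str, list[float]] = {name: [] for name in metrics}
            undef = {name: 0 for name in metrics}
            edge_loss = []
            for _ in range(reps):
                sub = fn(g, frac, rng)
                if mode == "nodes_uniform" and g.m > 0:
                    edge_loss.append(1.0 - sub.m / g.m)
                for name in metrics:
                    val = _METRICS[name](sub)
                    if is_defined(val):
                        vals[name].append(float(val))
                    else:
                        undef[name] += 1
            for name in metrics:
                defined = vals[name]
                mean_sub = float(np.mean(defined)) if defined else float("nan")
                orig = base[name]
                orig_f = float(orig) if is_defined(orig) else float("nan")
                rows.append(
                    {
                        "mode": mode,
                        "fraction": frac,
                        "metric": name,
                        "value": orig_f,
                        "mean_sub": mean_sub,
                        "abs_diff": abs(orig_f - mean_sub),
                        "undefined_frac": undef[name] / reps,
                        "edge_loss_frac": (
                            float(np.mean(edge_loss))
                            if mode == "nodes_uniform" and edge_loss
                            else float("nan")
                        ),
                    }
                )
    return pd.DataFrame(rows)
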