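"""Sweep harness: metric curves vs density and coefficient-of-variation
summaries across network size and density.

A sweep evaluates heterogeneity indices on graphs from the requested
families over a (size, density) grid.  Stochastic families are averaged
over repeated seeded draws; the extremal quasi-star and quasi-complete
families are deterministic, one graph per grid point (m = round(d * N)
edges, so every integer-percentage density is achievable).

The coefficient of variation (sample standard deviation over mean)
quantifies how sensitive an index is to size at fixed density
(``cov_wrt_size``) and to density at fixed size (``cov_wrt_density``);
an index that truly normalises out a nuisance parameter scores near zero.
Undefined index values (rho with isolated nodes, J on empty/complete
graphs) are excluded from means and counted per grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generators import build_graph
from .graph import Graph, round_half_away
from .metrics import (
    avg_degree_normalization,
    degree_irregularity,
    degree_variance,
    heterogeneity_index,
    max_lower_bound,
    normalized_degree_variance,
    quasistar_normalization,
)
from .undefined import ZERO_MEAN, MetricValue, Undefined, is_defined

__all__ = [
    "SweepResult",
    "CovSummary",
    "metric_sweep",
    "coefficient_of_variation",
    "cov_wrt_size",
    "cov_wrt_density",
    "lower_bound_survey",
    "default_density_grid",
    "METRIC_FUNCS",
]

DETERMINISTIC_FAMILIES = {"quasi_star", "quasi_complete"}


def _rho_or_undefined(g: Graph) -> MetricValue:
    return heterogeneity_index(g) if g.n >= 3 else Undefined("n_below_3")


METRIC_FUNCS = {
    "v": degree_variance,
    "vbar": normalized_degree_variance,
    "J": quasistar_normalization,
    "sigma2": avg_degree_normalization,
    "rho": _rho_or_undefined,
    "irr": degree_irregularity,
}


@dataclass(frozen=True)
class SweepResult:
    """Grid of mean metric values: one row per (family, n, density, metric)."""

    table: pd.DataFrame  # columns: family, n, density, metric, mean, reps, undefined

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.table)


@dataclass(frozen=True)
class CovSummary:
    """Per (family, metric): averaged coefficient of variation."""

    table: pd.DataFrame  # columns: family, metric, cov


def default_density_grid() -> list[float]:
    """Integer-percentage densities 1%..99%."""
    return [p / 100 for p in range(1, 100)]


def metric_sweep(
    families: list[str],
    sizes: list[int],
    densities: list[float],
    reps: int,
    seed: int,
    metrics: tuple[str, ...] = ("vbar", "J", "sigma2", "rho"),
) -> SweepResult:
    """Mean index values over a (family, size, density) grid.

    Stochastic families are averaged over ``reps`` seeded draws; extremal
    families are evaluated once (they are deterministic).  Undefined values
    are excluded from the mean and counted.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if any(not 0.0 < d < 1.0 for d in densities):
        raise ValueError("densities must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for family in families:
        n_reps = 1 if family in DETERMINISTIC_FAMILIES else reps
        for n in sizes:
            max_m = n * (n - 1) // 2
            for d in densities:
                m = round_half_away(d * max_m)
                acc: dict[str, list[float]] = {name: [] for name in metrics}
                undef = {name: 0 for name in metrics}
                for _ in range(n_reps):
                    g = build_graph(family, n, m, rng)
                    for name in metrics:
                        val = METRIC_FUNCS[name](g)
                        if is_defined(val):
                            acc[name].append(float(val))
                        else:
                            undef[name] += 1
                for name in metrics:
                    vals = acc[name]
                    rows.append(
                        {
                            "family": family,
                            "n": n,
                            "density": d,
                            "metric": name,
                            "mean": float(np.mean(vals)) if vals else float("nan"),
                            "reps": n_reps,
                            "undefined": undef[name],
                        }
                    )
    return SweepResult(pd.DataFrame(rows))


def coefficient_of_variation(values) -> MetricValue:
    """Sample standard deviation (n-1 denominator) divided by the mean.

    Undefined when the mean is zero.  A constant list gives exactly 0.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("coefficient of variation of an empty list")
    mean = arr.mean()
    if mean == 0.0:
        return Undefined(ZERO_MEAN)
    if arr.size == 1 or np.all(arr == arr[0]):
        return 0.0
    return float(arr.std(ddof=1) / mean)


def _cov_grouped(sweep: SweepResult, across: str, within: str) -> CovSummary:
    """CoV of the mean metric across `across`, per `within` level, averaged."""
    df = sweep.table.dropna(subset=["mean"])
    rows = []
    for (family, metric), grp in df.groupby(["family", "metric"], sort=True):
        covs = []
        for _, sub in grp.groupby(within, sort=True):
            if sub[across].nunique() < 2:
                continue
            c = coefficient_of_variation(sub["mean"].to_numpy())
            if is_defined(c):
                covs.append(float(c))
        rows.append(
            {
                "family": family,
                "metric": metric,
                "cov": float(np.mean(covs)) if covs else float("nan"),
            }
        )
    return CovSummary(pd.DataFrame(rows))


def cov_wrt_size(sweep: SweepResult) -> CovSummary:
    """CoV across network sizes at each density, averaged over densities."""
    return _cov_grouped(sweep, across="n", within="density")


def cov_wrt_density(sweep: SweepResult) -> CovSummary:
    """CoV across densities at each network size, averaged over sizes."""
    return _cov_grouped(sweep, across="density", within="n")


def lower_bound_survey(graphs: dict[str, Graph] | list[Graph]) -> pd.DataFrame:
    """Per graph: v̄, its maximum degree-multiplicity lower bound, their
    ratio, the relative degree achieving the bound and whether that degree
    exceeds the average degree.

    Regular graphs are reported with bound 0 and an undefined ratio.
    """
    if isinstance(graphs, list):
        graphs = {f"g{i}": g for i, g in enumerate(graphs)}
    rows = []
    for name, g in graphs.items():
        vbar = normalized_degree_variance(g)
        if not 0 < g.m < g.max_edges:
            raise ValueError(f"graph {name!r} is empty or complete")
        res = max_lower_bound(g)
        rows.append(
            {
                "name": name,
                "n": g.n,
                "m": g.m,
                "vbar": vbar,
                "bound": res.bound,
                "ratio": vbar / res.bound if res.bound > 0 else float("nan"),
                "argmax_degree": res.argmax_degree,
                "argmax_relative_degree": (
                    float(res.argmax_relative_degree)
                    if is_defined(res.argmax_relative_degree)
                    else float("nan")
                ),
                "above_average_degree": (
                    res.argmax_degree > 2 * g.m / g.n
                    if res.argmax_degree is not None
                    else False
                ),
            }
        )
    return pd.DataFrame(rows)
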