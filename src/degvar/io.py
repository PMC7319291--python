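"""Readers, writers and the fixture catalogue.

Edge lists are whitespace-separated pairs per line with an optional third
weight column and ``#`` comments; node labels are arbitrary strings, mapped
to internal 0-based indices with the label table preserved on the Graph.
Adjacency / weight matrices are square numeric CSV, required symmetric
within 1e-9.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .graph import Graph, WeightedMatrix
from .metrics import HeterogeneityReport

logger = logging.getLogger(__name__)

__all__ = [
    "read_graph",
    "read_weighted_matrix",
    "write_graph",
    "write_report",
    "read_report",
    "fixture_catalogue",
]


def _read_edgelist(path: Path) -> Graph:
    labels: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    n_self_loops = 0
    n_duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            a, b = parts[0], parts[1]
            if len(parts) == 3:
                try:
                    float(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: weight column is not numeric"
                    ) from exc
            for lab in (a, b):
                if lab not in labels:
                    labels[lab] = len(labels)
            if a == b:
                n_self_loops += 1
                continue
            i, j = labels[a], labels[b]
            e = (i, j) if i < j else (j, i)
            if e in pairs:
                n_duplicates += 1
            pairs.add(e)
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self_loops)
    if n_duplicates:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_duplicates)
    names = sorted(labels, key=labels.get)
    return Graph(len(labels), frozenset(pairs), tuple(names))


def _read_adjacency(path: Path) -> Graph:
    w = np.loadtxt(path, delimiter=",", ndmin=2)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: adjacency matrix is not square {w.shape}")
    if not np.allclose(w, w.T, atol=1e-9, rtol=0.0):
        raise ValueError(f"{path}: adjacency matrix is not symmetric")
    n = w.shape[0]
    if np.any(np.diag(w) != 0):
        logger.warning("%s: nonzero diagonal entries dropped", path)
    iu, ju = np.triu_indices(n, k=1)
    nz = w[iu, ju] != 0
    return Graph(n, frozenset(zip(iu[nz].tolist(), ju[nz].tolist())))


def read_graph(path: str | Path, format: str = "edgelist") -> Graph:
    """Read a simple undirected graph from an edge list or adjacency CSV.

    Duplicate edges are collapsed and self-loops dropped, each with a
    warning; node labels are preserved on the returned Graph.
    """
    path = Path(path)
    if format == "edgelist":
        return _read_edgelist(path)
    if format == "adjacency":
        return _read_adjacency(path)
    raise ValueError(f"unknown format {format!r}")


def read_weighted_matrix(path: str | Path) -> WeightedMatrix:
    """Read a symmetric nonnegative weight matrix from CSV."""
    w = np.loadtxt(Path(path), delimiter=",", ndmin=2)
    np.fill_diagonal(w, 0.0)
    return WeightedMatrix(0.5 * (w + w.T) if np.allclose(w, w.T, atol=1e-9) else w)


def write_graph(g: Graph, path: str | Path) -> None:
    """Write an edge list, using the graph's label table if present."""
    lab = g.labels or tuple(str(i) for i in range(g.n))
    with open(path, "w") as fh:
        fh.write(f"# n={g.n} m={g.m}\n")
        for i, j in sorted(g.edges):
            fh.write(f"{lab[i]}\t{lab[j]}\n")


_REPORT_COLUMNS = [
    "name", "n", "m", "d", "v", "v_bar", "irr",
    "J", "J_reason", "sigma2", "sigma2_reason", "rho", "rho_reason",
]


def write_report(
    reports: dict[str, HeterogeneityReport] | Iterable[HeterogeneityReport],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Serialise heterogeneity reports, one row per graph.

    Undefined values are emitted as "NA" with the reason in a companion
    column; numeric values round-trip to full precision.
    """
    if not isinstance(reports, dict):
        reports = {f"g{i}": r for i, r in enumerate(reports)}
    records = []
    for name, rep in reports.items():
        rec = {"name": name, **rep.to_record()}
        records.append({c: rec.get(c, "") for c in _REPORT_COLUMNS})
    if format == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
        return
    if format == "tsv":
        df = pd.DataFrame(records, columns=_REPORT_COLUMNS)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return
    raise ValueError(f"unknown format {format!r}")


def read_report(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh), columns=_REPORT_COLUMNS)
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"J": str, "sigma2": str, "rho": str})


def fixture_catalogue(seed: int = 0) -> dict[str, Graph]:
    """Deterministic named suite of graphs spanning every family.

    Contains stars, cycles, paths, complete graphs, perfect quasi-stars and
    quasi-completes at n in {4, 6, 8, 16}, plus seeded draws from each
    random ensemble.  The same seed always yields the identical catalogue.
    """
    from . import generators as gen
    from .graph import threshold_to_density

    rng = np.random.default_rng(seed)
    cat: dict[str, Graph] = {}
    for n in (4, 6, 8, 16):
        cat[f"star_{n}"] = gen.star_graph(n)
        cat[f"cycle_{n}"] = gen.cycle_graph(n)
        cat[f"path_{n}"] = gen.path_graph(n)
        cat[f"complete_{n}"] = gen.complete_graph(n)
        for r, m, _ in gen.perfect_quasistar_densities(n):
            if 0 < m < n * (n - 1) // 2:
                cat[f"pqs_{n}_r{r}"] = gen.quasi_star(n, m)
                cat[f"pqc_{n}_r{r}"] = gen.quasi_complete(n, n * (n - 1) // 2 - m)
    for n in (8, 16, 32):
        max_m = n * (n - 1) // 2
        cat[f"gnm_{n}"] = gen.er_gnm(n, max_m // 4, rng)
        cat[f"gnp_{n}"] = gen.er_gnp(n, 0.3, rng)
        cat[f"wer_{n}"] = threshold_to_density(gen.weighted_er(n, rng), 0.25)
        cat[f"rgg_{n}"] = threshold_to_density(
            gen.random_geometric_weighted(n, rng), 0.25
        )
    for n in (32, 64):
        cat[f"sf_{n}"] = gen.scale_free_core(n, 0.125, 0.0625, rng)
    return cat
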