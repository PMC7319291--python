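"""Flagged missing values for heterogeneity indices.

Several indices are undefined on some graphs (e.g. the heterogeneity index
rho on graphs with isolated nodes, the quasi-star normalisation J on empty
or complete graphs).  Sweeps and robustness tables must be able to count
such failures, so an undefined result is a value carrying a reason code,
never a silent zero and never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

# reason codes
ISOLATED_NODE = "isolated_node"
EMPTY_GRAPH = "empty_graph"
REGULAR_REFERENCE = "quasistar_regular"
ZERO_MEAN = "zero_mean"
CONSTANT_DEGREES = "constant_degrees"
REGULAR_GRAPH = "regular_graph"


@dataclass(frozen=True)
class Undefined:
    """A flagged missing metric value with a machine-readable reason."""

    reason: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Undefined({self.reason!r})"


MetricValue = float | Undefined


def is_defined(x: MetricValue) -> bool:
    return not isinstance(x, Undefined)


def as_float(x: MetricValue) -> float:
    """Collapse to a float, mapping undefined values to NaN."""
    return float("nan") if isinstance(x, Undefined) else float(x)
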