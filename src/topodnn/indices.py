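"""Catalog of twelve degree-based topological indices and their evaluation.

A degree-based index of a graph G is either

    sum over edges uv of  f(d_u, d_v)      (sum aggregation), or
    product over edges uv of  f(d_u, d_v)  (product aggregation),

with f symmetric in the two endpoint degrees.  The catalog covers the
classical descriptors used in QSPR work: the Randic connectivity index and
its general-exponent form, the first and second Zagreb indices and their
multiplicative variants, the hyper-Zagreb and forgotten indices, the
atom-bond connectivity (ABC), sum-connectivity (SCI), geometric-arithmetic
(GA) and augmented Zagreb (AZI) indices.

Each index can be evaluated two independent ways: directly over the edges
of a graph (the brute-force oracle) or over a degree-pair edge partition
(the closed-form route).  The two must always agree; the test suite holds
them to that.

Multiplicative indices explode quickly (a product over thousands of edges
of integer terms), so product-aggregated values always carry an exact
arbitrary-precision integer plus its base-10 logarithm.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Callable
from dataclasses import dataclass

from .graph_core import EdgePartition, Graph, degree_map, edge_partition

__all__ = [
    "IndexDefinition",
    "IndexValue",
    "IndexDomainError",
    "index_catalog",
    "get_index",
    "index_names",
    "edge_term",
    "evaluate_on_graph",
    "evaluate_on_partition",
    "log_space_product",
]

logger = logging.getLogger(__name__)


class IndexDomainError(ValueError):
    """Degree pair outside an index's domain (e.g. AZI on two degree-1 ends)."""


@dataclass(frozen=True)
class IndexDefinition:
    """A named edge functional plus its aggregation mode.

    ``term`` is the symmetric real-valued functional of (d_u, d_v);
    ``exact_term`` returns the same value as an exact integer when the
    functional is integer-valued on integer degrees (else ``None``), which
    drives exact big-integer evaluation.  ``needs_alpha`` marks the general
    Randic index, the one parametric entry.
    """

    name: str
    aggregation: str  # "sum" | "product"
    term: Callable[[int, int, float | None], float]
    exact_term: Callable[[int, int, float | None], int | None]
    needs_alpha: bool = False


@dataclass(frozen=True)
class IndexValue:
    """An evaluated descriptor.

    ``exact`` is set whenever every edge term is an exact integer (all
    product-type indices; the integer-valued sum-type ones).  ``log10`` is
    always set for product aggregation so values past float range stay
    usable.  ``value`` is ``inf`` when the exact integer exceeds float
    range.
    """

    name: str
    value: float
    alpha: float | None = None
    exact: int | None = None
    log10: float | None = None


def _no_exact(a: int, b: int, alpha: float | None) -> None:
    return None


def _randic(a: int, b: int, alpha: float | None) -> float:
    return 1.0 / math.sqrt(a * b)


def _general_randic(a: int, b: int, alpha: float | None) -> float:
    if alpha is None:
        raise IndexDomainError("general_randic requires an exponent alpha")
    return float(a * b) ** alpha


def _general_randic_exact(a: int, b: int, alpha: float | None) -> int | None:
    # exact only at non-negative integer exponents
    if alpha is None or alpha < 0 or float(alpha) != int(alpha):
        return None
    return (a * b) ** int(alpha)


def _zagreb1(a: int, b: int, alpha: float | None) -> float:
    return float(a + b)


def _zagreb1_exact(a: int, b: int, alpha: float | None) -> int:
    return a + b


def _zagreb2(a: int, b: int, alpha: float | None) -> float:
    return float(a * b)


def _zagreb2_exact(a: int, b: int, alpha: float | None) -> int:
    return a * b


def _hyper_zagreb(a: int, b: int, alpha: float | None) -> float:
    return float((a + b) ** 2)


def _hyper_zagreb_exact(a: int, b: int, alpha: float | None) -> int:
    return (a + b) ** 2


def _forgotten(a: int, b: int, alpha: float | None) -> float:
    return float(a * a + b * b)


def _forgotten_exact(a: int, b: int, alpha: float | None) -> int:
    return a * a + b * b


def _abc(a: int, b: int, alpha: float | None) -> float:
    # a + b == 2 gives a zero numerator under the root, not a domain error
    return math.sqrt((a + b - 2) / (a * b))


def _sci(a: int, b: int, alpha: float | None) -> float:
    return 1.0 / math.sqrt(a + b)


def _ga(a: int, b: int, alpha: float | None) -> float:
    return 2.0 * math.sqrt(a * b) / (a + b)


def _azi(a: int, b: int, alpha: float | None) -> float:
    return (a * b / (a + b - 2)) ** 3


_CATALOG: tuple[IndexDefinition, ...] = (
    IndexDefinition("randic", "sum", _randic, _no_exact),
    IndexDefinition("general_randic", "sum", _general_randic,
                    _general_randic_exact, needs_alpha=True),
    IndexDefinition("zagreb1", "sum", _zagreb1, _zagreb1_exact),
    IndexDefinition("zagreb2", "sum", _zagreb2, _zagreb2_exact),
    IndexDefinition("mult_zagreb1", "product", _zagreb1, _zagreb1_exact),
    IndexDefinition("mult_zagreb2", "product", _zagreb2, _zagreb2_exact),
    IndexDefinition("hyper_zagreb", "sum", _hyper_zagreb, _hyper_zagreb_exact),
    IndexDefinition("abc", "sum", _abc, _no_exact),
    IndexDefinition("sci", "sum", _sci, _no_exact),
    IndexDefinition("ga", "sum", _ga, _no_exact),
    IndexDefinition("forgotten", "sum", _forgotten, _forgotten_exact),
    IndexDefinition("azi", "sum", _azi, _no_exact),
)

_BY_NAME = {d.name: d for d in _CATALOG}


def index_catalog() -> tuple[IndexDefinition, ...]:
    """The fixed, ordered catalog of twelve index definitions."""
    return _CATALOG


def index_names() -> tuple[str, ...]:
    return tuple(d.name for d in _CATALOG)


def get_index(name: str) -> IndexDefinition:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown index {name!r}; catalog: {', '.join(_BY_NAME)}"
        ) from None


def _check_domain(definition: IndexDefinition, d_u: int, d_v: int) -> None:
    if d_u < 1 or d_v < 1:
        raise IndexDomainError(
            f"degrees must be >= 1 on an edge, got ({d_u}, {d_v})"
        )
    if definition.name == "azi" and d_u + d_v == 2:
        raise IndexDomainError(
            "azi is undefined on an edge with both endpoint degrees 1 "
            "(zero denominator)"
        )


def edge_term(
    definition: IndexDefinition, d_u: int, d_v: int, alpha: float | None = None
) -> float:
    """The single-edge contribution f(d_u, d_v); symmetric and finite."""
    _check_domain(definition, d_u, d_v)
    return definition.term(d_u, d_v, alpha)


def _finalize(
    definition: IndexDefinition,
    alpha: float | None,
    total: float,
    exact: int | None,
    log10: float | None,
) -> IndexValue:
    if exact is not None:
        try:
            total = float(exact)
        except OverflowError:
            total = math.inf
    return IndexValue(
        name=definition.name,
        alpha=alpha if definition.needs_alpha else None,
        value=total,
        exact=exact,
        log10=log10,
    )


def _evaluate(
    definition: IndexDefinition,
    class_iter,  # iterable of ((d_u, d_v), count)
    n_edges: int,
    alpha: float | None,
) -> IndexValue:
    if n_edges == 0:
        # aggregation identities; the descriptors are meant for graphs
        # with edges, so flag it
        logger.warning(
            "index %s evaluated on an edgeless graph; returning the "
            "aggregation identity", definition.name,
        )
        if definition.aggregation == "product":
            return _finalize(definition, alpha, 1.0, 1, 0.0)
        return _finalize(definition, alpha, 0.0, 0, None)

    if definition.aggregation == "product":
        exact = 1
        log10 = 0.0
        for (a, b), count in class_iter:
            _check_domain(definition, a, b)
            t = definition.exact_term(a, b, alpha)
            if t is None or t <= 0:
                raise IndexDomainError(
                    f"product index {definition.name} needs positive "
                    f"integer terms, got {t!r} at {(a, b)}"
                )
            exact *= t ** count
            log10 += count * math.log10(t)
        return _finalize(definition, alpha, math.nan, exact, log10)

    total = 0.0
    exact: int | None = 0
    for (a, b), count in class_iter:
        _check_domain(definition, a, b)
        total += count * definition.term(a, b, alpha)
        if exact is not None:
            t = definition.exact_term(a, b, alpha)
            exact = None if t is None else exact + count * t
    return _finalize(definition, alpha, total, exact, None)


def evaluate_on_graph(
    graph: Graph, definition: IndexDefinition, alpha: float | None = None
) -> IndexValue:
    """Brute-force evaluation: iterate every edge of the graph exactly once.

    This is the oracle path that closed-form and partition evaluations are
    verified against.
    """
    degrees = degree_map(graph)
    classes = (((degrees[u], degrees[v]), 1) for u, v in graph.edges)
    return _evaluate(definition, classes, graph.num_edges, alpha)


def evaluate_on_partition(
    partition: EdgePartition,
    definition: IndexDefinition,
    alpha: float | None = None,
) -> IndexValue:
    """Edge-partition evaluation: weight each class's term by its count.

    Agrees with :func:`evaluate_on_graph` on the partition's source graph
    exactly for integer-valued indices and to 1e-9 relative otherwise.
    """
    return _evaluate(
        definition, partition.classes.items(), partition.total_edges, alpha
    )


def log_space_product(
    partition: EdgePartition,
    definition: IndexDefinition,
    alpha: float | None = None,
) -> float:
    """log10 of a product-aggregated index, computed without the big product.

    Returns ``sum(count * log10(term))`` over classes; overflow-free for
    arbitrarily large graphs.
    """
    if definition.aggregation != "product":
        raise ValueError(f"{definition.name} is not product-aggregated")
    total = 0.0
    for (a, b), count in partition.classes.items():
        _check_domain(definition, a, b)
        t = definition.term(a, b, alpha)
        if t <= 0:
            raise IndexDomainError(
                f"nonpositive term {t!r} at class {(a, b)} for "
                f"{definition.name}"
            )
        total += count * math.log10(t)
    return total


def evaluate_all_on_graph(
    graph: Graph, names=None, alpha: float | None = None
) -> list[IndexValue]:
    """Convenience: evaluate a selection (default: all twelve) on a graph."""
    selection = index_names() if names is None else tuple(names)
    return [evaluate_on_graph(graph, get_index(n), alpha) for n in selection]
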