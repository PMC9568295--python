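"""The layered fully-connected graph family DNN(M; N1..Nr; N).

A feed-forward network with an input layer of M nodes, hidden layers of
widths N1..Nr and an output layer of N nodes, where every node of a layer
is joined to every node of the next layer, is — as a graph — a chain of
complete bipartite blocks.  All nodes in one layer share a degree:

    layer 0 (input):     N1
    layer i (hidden):    N_{i-1} + N_{i+1}   with N0 := M, N_{r+1} := N
    layer r+1 (output):  Nr

so the edge partition by endpoint-degree pairs has at most r+1 classes,
one per consecutive layer pair, and every degree-based index has a closed
form in the widths.  This module builds the explicit graph, derives the
closed-form partition, evaluates any catalog index from it, and sweeps
index growth with depth.

The closed forms here are generated from the consecutive-layer partition,
which is valid for every depth r >= 1.  A separate literal evaluator
(:func:`literal_closed_form`) transcribes the traditional printed
expressions — two head terms, an interior sum over i = 2..r-2, two tail
terms — and serves purely as a cross-check for r >= 3, where those
expressions are well formed.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .graph_core import EdgePartition, Graph, GraphValidationError, build_graph
from .indices import (
    IndexValue,
    evaluate_on_graph,
    evaluate_on_partition,
    get_index,
    index_names,
)

__all__ = [
    "DNNSpec",
    "layer_degree",
    "degree_profile",
    "build_dnn_graph",
    "closed_form_partition",
    "closed_form_index",
    "literal_closed_form",
    "growth_profile",
]


@dataclass(frozen=True)
class DNNSpec:
    """Architecture (M; N1..Nr; N) parameterizing the graph family.

    All widths are positive integers and there is at least one hidden
    layer.  ``num_nodes`` and ``num_edges`` are the counts the complete
    bipartite wiring implies.
    """

    input_width: int
    hidden_widths: tuple[int, ...]
    output_width: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_widths", tuple(self.hidden_widths))
        widths = (self.input_width, *self.hidden_widths, self.output_width)
        if len(self.hidden_widths) < 1:
            raise ValueError("need at least one hidden layer")
        if any(not isinstance(w, int) or w < 1 for w in widths):
            raise ValueError(f"all layer widths must be positive integers: {widths}")

    @classmethod
    def from_layer_widths(cls, widths: Sequence[int]) -> "DNNSpec":
        """Parse the flat notation DNN(a1, ..., ak): input, hidden..., output.

        Requires k >= 3 (at least one hidden layer).
        """
        widths = tuple(widths)
        if len(widths) < 3:
            raise ValueError(
                f"architecture needs >= 3 layers (input, hidden..., output); "
                f"got {len(widths)}"
            )
        return cls(widths[0], widths[1:-1], widths[-1])

    @property
    def depth(self) -> int:
        """Number of hidden layers r."""
        return len(self.hidden_widths)

    @property
    def layer_widths(self) -> tuple[int, ...]:
        """Widths of all r+2 layers, input first."""
        return (self.input_width, *self.hidden_widths, self.output_width)

    @property
    def num_nodes(self) -> int:
        return sum(self.layer_widths)

    @property
    def num_edges(self) -> int:
        w = self.layer_widths
        return sum(w[i] * w[i + 1] for i in range(len(w) - 1))

    def __str__(self) -> str:
        hidden = ",".join(str(w) for w in self.hidden_widths)
        return f"DNN({self.input_width};[{hidden}];{self.output_width})"


def layer_degree(spec: DNNSpec, layer_index: int) -> int:
    """Shared degree of every node in the given layer (0 = input, r+1 = output).

    A node's neighbours are exactly the nodes of the adjacent layers, so
    its degree is the sum of the neighbouring widths; the input and output
    layers have a single neighbour layer each.
    """
    w = spec.layer_widths
    last = spec.depth + 1
    if not 0 <= layer_index <= last:
        raise IndexError(f"layer index {layer_index} out of range [0, {last}]")
    below = w[layer_index - 1] if layer_index > 0 else 0
    above = w[layer_index + 1] if layer_index < last else 0
    return below + above


def degree_profile(spec: DNNSpec) -> tuple[int, ...]:
    """Per-layer node degree for all r+2 layers."""
    return tuple(layer_degree(spec, i) for i in range(spec.depth + 2))


def node_label(layer: int, k: int) -> str:
    """Deterministic node identifier: layer number and 0-based position."""
    return f"L{layer}:{k}"


def build_dnn_graph(spec: DNNSpec) -> Graph:
    """Explicit construction: complete bipartite wiring between consecutive layers."""
    w = spec.layer_widths
    nodes = [node_label(i, k) for i in range(len(w)) for k in range(w[i])]
    edges = [
        (node_label(i, a), node_label(i + 1, b))
        for i in range(len(w) - 1)
        for a in range(w[i])
        for b in range(w[i + 1])
    ]
    return build_graph(nodes, edges)


def closed_form_partition(spec: DNNSpec) -> EdgePartition:
    """Edge partition derived from the widths alone, no graph built.

    Each consecutive layer pair (i, i+1) contributes the class with degree
    pair (layer_degree(i), layer_degree(i+1)) and count width_i * width_{i+1};
    coincident canonical pairs merge.  Equals
    ``edge_partition(build_dnn_graph(spec))`` exactly.
    """
    w = spec.layer_widths
    degs = degree_profile(spec)
    classes: dict[tuple[int, int], int] = {}
    for i in range(len(w) - 1):
        a, b = degs[i], degs[i + 1]
        pair = (a, b) if a <= b else (b, a)
        classes[pair] = classes.get(pair, 0) + w[i] * w[i + 1]
    return EdgePartition(classes=dict(sorted(classes.items())))


def closed_form_index(
    spec: DNNSpec, index_name: str, alpha: float | None = None
) -> IndexValue:
    """Evaluate a catalog index from the closed-form partition.

    Must match brute-force evaluation on the constructed graph exactly for
    integer-valued indices and to 1e-9 relative otherwise; the test suite
    and ``topodnn verify`` enforce this.
    """
    definition = get_index(index_name)
    return evaluate_on_partition(closed_form_partition(spec), definition, alpha)


# --- literal transcription of the traditional r >= 3 closed forms ----------
#
# For r >= 3 the partition has the displayed layout: head classes
#   (N1, M+N2) x M*N1          and   (M+N2, N1+N3) x N1*N2,
# interior classes for i = 2..r-2
#   (N_{i-1}+N_{i+1}, N_i+N_{i+2}) x N_i*N_{i+1},
# and tail classes
#   (N_{r-2}+N_r, N_{r-1}+N) x N_{r-1}*N_r   and   (N_{r-1}+N, N_r) x N_r*N.
# The evaluators below transcribe those expressions term for term and exist
# only to cross-check the generic partition route.


def _literal_classes(spec: DNNSpec) -> list[tuple[int, int, int]]:
    """(d_u, d_v, count) triples in the displayed r >= 3 layout, unmerged."""
    if spec.depth < 3:
        raise ValueError("literal closed forms are defined for depth r >= 3")
    M, N = spec.input_width, spec.output_width
    n = {i: w for i, w in enumerate(spec.hidden_widths, start=1)}
    r = spec.depth
    rows = [
        (n[1], M + n[2], M * n[1]),
        (M + n[2], n[1] + n[3], n[1] * n[2]),
    ]
    for i in range(2, r - 1):  # interior sum, empty at r = 3
        rows.append((n[i - 1] + n[i + 1], n[i] + n[i + 2], n[i] * n[i + 1]))
    rows.append((n[r - 2] + n[r], n[r - 1] + N, n[r - 1] * n[r]))
    rows.append((n[r - 1] + N, n[r], n[r] * N))
    return rows


_LITERAL_NAMES = (
    "general_randic", "zagreb1", "zagreb2",
    "mult_zagreb1", "mult_zagreb2", "forgotten", "hyper_zagreb",
)


def literal_closed_form(
    spec: DNNSpec, index_name: str, alpha: float | None = None
):
    """Verbatim evaluator of the traditional printed expressions (r >= 3).

    Covers the general Randic index (the printed "Randic" result is its
    alpha = +1/2 case), both Zagreb indices and their multiplicative
    variants, and the forgotten and hyper-Zagreb indices.  Returns a float
    for sum-type indices and an exact big integer for the multiplicative
    ones.  Independent of :func:`closed_form_partition` (no
    canonicalization or merging); used only as a cross-check.
    """
    if index_name not in _LITERAL_NAMES:
        raise KeyError(
            f"no literal transcription for {index_name!r}; "
            f"available: {', '.join(_LITERAL_NAMES)}"
        )
    rows = _literal_classes(spec)
    if index_name == "general_randic":
        if alpha is None:
            raise ValueError("general_randic requires alpha")
        return sum(c * float(a * b) ** alpha for a, b, c in rows)
    if index_name == "zagreb1":
        return sum(c * (a + b) for a, b, c in rows)
    if index_name == "zagreb2":
        return sum(c * a * b for a, b, c in rows)
    if index_name == "forgotten":
        return sum(c * (a * a + b * b) for a, b, c in rows)
    if index_name == "hyper_zagreb":
        return sum(c * (a + b) ** 2 for a, b, c in rows)
    if index_name == "mult_zagreb1":
        return math.prod((a + b) ** c for a, b, c in rows)
    # mult_zagreb2
    return math.prod((a * b) ** c for a, b, c in rows)


def verify_against_oracle(
    spec: DNNSpec,
    alphas: Sequence[float] = (-0.5, 0.5, 1.0, 2.0),
    rel_tol: float = 1e-9,
) -> list[str]:
    """Check every closed form against brute force on the built graph.

    Compares the closed-form partition with the brute-force edge partition,
    then every catalog index (general Randic at each exponent in
    ``alphas``) between the two evaluation routes: exact equality whenever
    both sides carry exact integers, ``rel_tol`` relative otherwise, and
    additionally on log10 for the multiplicative indices.  Returns a list
    of human-readable mismatch descriptions; empty means verified.
    """
    from .graph_core import edge_partition

    mismatches: list[str] = []
    graph = build_dnn_graph(spec)
    brute = edge_partition(graph)
    closed = closed_form_partition(spec)
    if brute != closed:
        mismatches.append(
            f"{spec}: partition mismatch closed={closed.classes} "
            f"brute={brute.classes}"
        )
    for name in index_names():
        definition = get_index(name)
        cases = alphas if definition.needs_alpha else (None,)
        for a in cases:
            cf = closed_form_index(spec, name, a)
            oc = evaluate_on_graph(graph, definition, a)
            if cf.exact is not None and oc.exact is not None:
                ok = cf.exact == oc.exact
            else:
                ok = math.isclose(
                    cf.value, oc.value, rel_tol=rel_tol, abs_tol=1e-12
                )
            if ok and cf.log10 is not None:
                ok = math.isclose(
                    cf.log10, oc.log10, rel_tol=rel_tol, abs_tol=1e-12
                )
            if not ok:
                mismatches.append(
                    f"{spec}: {name}(alpha={a}) closed={cf} oracle={oc}"
                )
    return mismatches


def growth_profile(
    base_spec: DNNSpec,
    max_depth: int,
    index_names_: Iterable[str] | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Index values as hidden depth grows from 1 to ``max_depth``.

    The depth-d member keeps the input and output widths and the first
    min(d, r) hidden widths of ``base_spec``, padding with the last hidden
    width when d exceeds r.  For a uniform-width family DNN(k; [k]*d; k)
    each added layer appends k^2 edges of class (2k, 2k) and changes no
    existing degree, so every sum-aggregated index with strictly positive
    terms grows strictly with depth.

    Returns a tidy table with columns depth, index, alpha, value, exact,
    log10 (exact rendered as string, empty when unset).
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    selection = tuple(index_names_) if index_names_ is not None else index_names()
    hidden = base_spec.hidden_widths
    rows = []
    for depth in range(1, max_depth + 1):
        widths = tuple(
            hidden[i] if i < len(hidden) else hidden[-1] for i in range(depth)
        )
        spec = DNNSpec(base_spec.input_width, widths, base_spec.output_width)
        for name in selection:
            iv = closed_form_index(spec, name, alpha)
            rows.append(
                {
                    "depth": depth,
                    "index": name,
                    "alpha": iv.alpha,
                    "value": iv.value,
                    "exact": "" if iv.exact is None else str(iv.exact),
                    "log10": iv.log10,
                }
            )
    return pd.DataFrame(rows, columns=["depth", "index", "alpha", "value", "exact", "log10"])
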