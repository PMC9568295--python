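"""Edge-list parsing, report writing, and the seeded spec generator.

Edge-list dialect: one edge per line, two tab-separated node labels,
lines starting with '#' and blank lines ignored, undirected, duplicate or
self-loop edges rejected with the offending line number.  Reports are TSV
or JSON with a fixed column order (index, alpha, value, exact, log10);
exact big integers are serialized as strings in JSON since numeric JSON
would silently lose precision in most consumers.
"""

from __future__ import annotations

import json
import random
from collections.abc import Iterable, Iterator
from pathlib import Path
from typing import IO, Sequence

from .dnn_family import DNNSpec
from .graph_core import EdgePartition, Graph, GraphValidationError, build_graph
from .indices import IndexValue

__all__ = [
    "EdgeListError",
    "read_edge_list",
    "write_edge_list",
    "format_report",
    "write_report",
    "random_spec_generator",
]

REPORT_COLUMNS = ("index", "alpha", "value", "exact", "log10")
PARTITION_COLUMNS = ("d_u", "d_v", "count")


class EdgeListError(ValueError):
    """Malformed or invalid edge-list input, with a line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def read_edge_list(path: str | Path) -> Graph:
    """Parse a TSV edge list into a validated simple graph.

    Node order is first-appearance order, so a written-then-read graph has
    an identical edge partition.
    """
    nodes: list[str] = []
    seen_nodes: set[str] = set()
    edges: list[tuple[str, str]] = []
    seen_edges: set[frozenset] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise EdgeListError(
                    f"expected 2 tab-separated fields, got {len(fields)}", lineno
                )
            u, v = (f.strip() for f in fields)
            if not u or not v:
                raise EdgeListError("empty node label", lineno)
            if u == v:
                raise EdgeListError(f"self-loop on node {u!r}", lineno)
            key = frozenset((u, v))
            if key in seen_edges:
                raise EdgeListError(f"duplicate edge ({u!r}, {v!r})", lineno)
            seen_edges.add(key)
            for label in (u, v):
                if label not in seen_nodes:
                    seen_nodes.add(label)
                    nodes.append(label)
            edges.append((u, v))
    if not nodes:
        raise EdgeListError("no edges found", 0)
    return build_graph(nodes, edges)


def write_edge_list(graph: Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, int):
        return str(x)
    return format(x, ".12g")


def format_report(
    values: Sequence[IndexValue],
    partition: EdgePartition | None = None,
    fmt: str = "tsv",
) -> str:
    """Render evaluated index values (and optionally the edge partition).

    TSV: a header row then one row per index; when a partition is given, a
    blank line and a second table with columns d_u, d_v, count.  JSON: an
    object with an ``indices`` array and an optional ``partition`` array.
    """
    if fmt == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        for iv in values:
            lines.append(
                "\t".join(
                    (iv.name, _fmt(iv.alpha), _fmt(iv.value), _fmt(iv.exact),
                     _fmt(iv.log10))
                )
            )
        if partition is not None:
            lines.append("")
            lines.append("\t".join(PARTITION_COLUMNS))
            for (a, b), count in partition.classes.items():
                lines.append(f"{a}\t{b}\t{count}")
        return "\n".join(lines) + "\n"
    if fmt == "json":
        payload: dict = {
            "indices": [
                {
                    "index": iv.name,
                    "alpha": iv.alpha,
                    "value": iv.value,
                    "exact": None if iv.exact is None else str(iv.exact),
                    "log10": iv.log10,
                }
                for iv in values
            ]
        }
        if partition is not None:
            payload["partition"] = [
                {"d_u": a, "d_v": b, "count": count}
                for (a, b), count in partition.classes.items()
            ]
        return json.dumps(payload, indent=2, sort_keys=False) + "\n"
    raise ValueError(f"unknown report format {fmt!r} (expected tsv or json)")


def write_report(
    values: Sequence[IndexValue],
    partition: EdgePartition | None,
    fmt: str,
    path: str | Path | IO[str],
) -> None:
    text = format_report(values, partition, fmt)
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


def random_spec_generator(
    seed: int, trials: int, max_depth: int, max_width: int
) -> Iterator[DNNSpec]:
    """Reproducible stream of random architectures for verification sweeps.

    Depth uniform on [1, max_depth]; every width uniform on [1, max_width].
    """
    if trials < 1 or max_depth < 1 or max_width < 1:
        raise ValueError("trials, max_depth and max_width must be >= 1")
    rng = random.Random(seed)
    for _ in range(trials):
        depth = rng.randint(1, max_depth)
        yield DNNSpec(
            input_width=rng.randint(1, max_width),
            hidden_widths=tuple(rng.randint(1, max_width) for _ in range(depth)),
            output_width=rng.randint(1, max_width),
        )
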