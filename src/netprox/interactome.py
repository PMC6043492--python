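"""Interactome graph model, edge-list / gene-set I/O, and degree binning.

The interactome is an undirected simple graph whose nodes are gene
identifiers (opaque strings; Entrez-style integers are the expected input)
and whose edges are experimentally supported protein-protein interactions.
All network distances in :mod:`netprox.proximity` are computed on this
graph, and the degree bins built here drive the degree-preserving null
model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import networkx as nx

__all__ = [
    "GeneSet",
    "DegreeBins",
    "EdgeListReport",
    "ParseError",
    "load_edge_list",
    "write_edge_list",
    "largest_connected_component",
    "build_degree_bins",
    "load_gene_sets",
    "write_gene_sets",
    "restrict_to_network",
]


class ParseError(ValueError):
    """Malformed input line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (a disease module or a drug's targets)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(str(m) for m in self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __contains__(self, gene: object) -> bool:
        return gene in self.members


@dataclass
class EdgeListReport:
    """Counts of lines dropped or collapsed while reading an edge list."""

    n_lines: int = 0
    n_edges: int = 0
    n_self_loops: int = 0
    n_duplicates: int = 0
    n_comments: int = 0


def _as_lines(source: str | Path | IO[str]) -> tuple[Iterable[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def load_edge_list(
    source: str | Path | IO[str],
    delimiter: str | None = None,
) -> tuple[nx.Graph, EdgeListReport]:
    """Read a two-column edge list into an undirected simple graph.

    Lines starting with ``#`` are comments; extra columns are ignored.
    ``delimiter=None`` splits on any whitespace (tabs included). Self-loops
    are dropped (the node is kept) and duplicate edges are collapsed, with
    counts recorded in the returned :class:`EdgeListReport`.

    Raises :class:`ParseError` on a line with fewer than two columns, and
    :class:`ValueError` on an input with no usable lines at all.
    """
    handle, owns = _as_lines(source)
    g = nx.Graph()
    report = EdgeListReport()
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                report.n_comments += 1
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise ParseError(
                    f"expected at least 2 columns, got {len(fields)}: {line!r}",
                    lineno,
                )
            report.n_lines += 1
            a, b = fields[0], fields[1]
            if a == b:
                report.n_self_loops += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                report.n_duplicates += 1
            else:
                g.add_edge(a, b)
    finally:
        if owns:
            handle.close()  # type: ignore[union-attr]
    if report.n_lines == 0:
        raise ValueError("edge list contains no data lines")
    report.n_edges = g.number_of_edges()
    return g, report


def write_edge_list(g: nx.Graph, target: str | Path | IO[str], delimiter: str = "\t") -> None:
    """Write the graph as a two-column edge list (one line per edge)."""
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as fh:
            write_edge_list(g, fh, delimiter)
        return
    for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
        target.write(f"{a}{delimiter}{b}\n")
    # isolated nodes are not representable in a pure edge list; callers that
    # need them round-tripped should serialize the node set separately


def largest_connected_component(g: nx.Graph) -> tuple[nx.Graph, int]:
    """Induced subgraph on the largest connected component.

    Returns the subgraph (a copy) and the number of dropped nodes. Ties in
    component size break toward the component containing the
    lexicographically smallest node identifier, for determinism.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    components = list(nx.connected_components(g))
    max_size = max(len(c) for c in components)
    best = min((c for c in components if len(c) == max_size), key=min)
    sub = g.subgraph(best).copy()
    return sub, g.number_of_nodes() - sub.number_of_nodes()


@dataclass
class DegreeBins:
    """Partition of the interactome's nodes into bins of similar degree.

    Nodes are first grouped by exact degree; ascending adjacent degree
    groups are then merged until every bin holds at least ``min_bin_size``
    nodes (a final undersized bin is merged into its lower neighbor). The
    degree-preserving null model replaces each node of a template set with
    a uniform draw from that node's bin, so hub structure is preserved.
    """

    bins: list[tuple[str, ...]]
    degree_ranges: list[tuple[int, int]]
    min_bin_size: int
    node_to_bin: dict[str, int] = field(repr=False)

    def bin_of(self, node: str) -> tuple[str, ...]:
        return self.bins[self.node_to_bin[node]]


def build_degree_bins(g: nx.Graph, min_bin_size: int = 100) -> DegreeBins:
    """Group nodes by degree and merge upward until bins reach ``min_bin_size``.

    With ``min_bin_size=1`` this yields one bin per distinct degree. A graph
    smaller than ``min_bin_size`` collapses into a single bin.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")

    by_degree: dict[int, list[str]] = {}
    for node, deg in g.degree():
        by_degree.setdefault(deg, []).append(node)

    bins: list[list[str]] = []
    ranges: list[tuple[int, int]] = []
    current: list[str] = []
    lo: int | None = None
    for deg in sorted(by_degree):
        if lo is None:
            lo = deg
        current.extend(by_degree[deg])
        if len(current) >= min_bin_size:
            bins.append(current)
            ranges.append((lo, deg))
            current, lo = [], None
    if current:
        if bins:
            bins[-1].extend(current)
            ranges[-1] = (ranges[-1][0], max(by_degree))
        else:
            bins.append(current)
            ranges.append((lo if lo is not None else 0, max(by_degree)))

    frozen = [tuple(sorted(b)) for b in bins]
    node_to_bin = {n: i for i, b in enumerate(frozen) for n in b}
    return DegreeBins(
        bins=frozen, degree_ranges=ranges, min_bin_size=min_bin_size, node_to_bin=node_to_bin
    )


def load_gene_sets(source: str | Path | IO[str]) -> list[GeneSet]:
    """Read gene sets from a GMT stream: name, description, members (tab-separated).

    Members are deduplicated; a line without members raises
    :class:`ParseError` with its line number. Sets are returned in input
    order.
    """
    handle, owns = _as_lines(source)
    sets: list[GeneSet] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line needs name, description, and >=1 member", lineno)
            name, members = fields[0], [f for f in fields[2:] if f]
            if not members:
                raise ParseError("GMT line has no members", lineno)
            sets.append(GeneSet(name=name, members=frozenset(members)))
    finally:
        if owns:
            handle.close()  # type: ignore[union-attr]
    return sets


def write_gene_sets(sets: Sequence[GeneSet], target: str | Path | IO[str]) -> None:
    """Write gene sets in GMT format (description column left as '-')."""
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8") as fh:
            write_gene_sets(sets, fh)
        return
    for s in sets:
        target.write("\t".join([s.name, "-"] + sorted(s.members)) + "\n")


def restrict_to_network(s: GeneSet, g: nx.Graph) -> tuple[GeneSet, frozenset[str]]:
    """Intersect a gene set with the interactome's node set.

    Returns the restricted set and the identifiers that were dropped. An
    empty intersection is returned as-is (with all members reported
    dropped); the caller decides whether that is an error.
    """
    kept = frozenset(m for m in s.members if m in g)
    dropped = s.members - kept
    return GeneSet(name=s.name, members=kept), dropped


def read_edge_list_string(text: str, delimiter: str | None = None) -> tuple[nx.Graph, EdgeListReport]:
    """Convenience wrapper: parse an edge list held in a string."""
    return load_edge_list(io.StringIO(text), delimiter=delimiter)
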