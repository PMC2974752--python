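"""I/O for PPI networks, complex catalogs, and annotation tables.

The network container is a plain :class:`networkx.Graph`: nodes are protein
IDs (opaque, case-sensitive strings), edges are undirected interactions.
Loading enforces the simple-graph contract — no self-loops, no duplicate
edges — so downstream degree/edge-count arithmetic (``k_v``, ``m``) is
well defined.  All file formats are UTF-8 text with ``#`` comment lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input lines; message carries the line number."""


@dataclass
class ComplexCatalog:
    """A catalog of known (or predicted) complexes.

    ``entries`` is a list of ``(name, member_set)`` pairs; names are kept
    only for reporting and play no role in matching.
    """

    entries: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def member_sets(self) -> list[frozenset[str]]:
        return [members for _, members in self.entries]


@dataclass
class AnnotationTable:
    """Protein -> set-of-labels mapping (GO slim terms or compartments)."""

    mapping: dict[str, set[str]] = field(default_factory=dict)

    def labels_of(self, protein: str) -> set[str]:
        """Labels of ``protein``; unknown proteins map to the empty set."""
        return self.mapping.get(protein, set())

    @property
    def label_universe(self) -> set[str]:
        """All distinct labels seen in the table."""
        out: set[str] = set()
        for labels in self.mapping.values():
            out |= labels
        return out

    @property
    def annotated_proteins(self) -> set[str]:
        """All proteins carrying at least one label."""
        return {p for p, labels in self.mapping.items() if labels}


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: str | Path, delimiter: str | None = None) -> nx.Graph:
    """Read a two-column edge list into a simple undirected graph.

    Self-loops are dropped and repeated pairs (in either order) are
    collapsed to a single edge; the counts of both are logged.  The default
    ``delimiter=None`` splits on any whitespace run, which covers both
    space- and tab-delimited exports.

    Raises
    ------
    ParseError
        If a non-comment line has fewer than two fields, or the file
        contains no edges at all.
    """
    graph = nx.Graph()
    n_self_loops = 0
    n_duplicates = 0
    for lineno, line in _data_lines(path):
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
        u, v = fields[0], fields[1]
        if u == v:
            n_self_loops += 1
            continue
        if graph.has_edge(u, v):
            n_duplicates += 1
            continue
        graph.add_edge(u, v)
    if graph.number_of_edges() == 0:
        raise ParseError(f"{path}: empty network")
    logger.info(
        "read %d nodes / %d edges from %s (dropped %d self-loops, %d duplicate edges)",
        graph.number_of_nodes(), graph.number_of_edges(), path, n_self_loops, n_duplicates,
    )
    return graph


def read_complex_catalog(
    path: str | Path,
    min_size: int = 3,
    has_name: bool = True,
    n_skip_fields: int = 0,
    delimiter: str | None = None,
) -> ComplexCatalog:
    """Read a complex catalog: one complex per line, tab/space separated.

    Parameters
    ----------
    min_size
        Complexes with fewer members (after within-line deduplication) are
        dropped.  The conventional catalog filter keeps complexes of at
        least 3 proteins.
    has_name
        If True, the first field of each line is the complex name; if
        False all fields are member IDs and a positional name is assigned.
    n_skip_fields
        Number of fields after the name to ignore (lets files written by
        :func:`write_complexes`, which carry size and density columns,
        round-trip back through this reader).
    """
    entries: list[tuple[str, frozenset[str]]] = []
    n_dropped = 0
    for lineno, line in _data_lines(path):
        fields = line.split(delimiter)
        if has_name:
            name, rest = fields[0], fields[1:]
        else:
            name, rest = f"complex_{len(entries) + n_dropped + 1}", fields
        members = frozenset(rest[n_skip_fields:])
        if not members:
            raise ParseError(f"{path}: line {lineno}: complex with zero members")
        if len(members) < min_size:
            n_dropped += 1
            continue
        entries.append((name, members))
    if n_dropped:
        logger.info("dropped %d complexes smaller than %d from %s", n_dropped, min_size, path)
    return ComplexCatalog(entries)


def write_complexes(complexes: Sequence, path: str | Path) -> None:
    """Write predicted complexes: rank, size, density score, sorted members.

    Accepts :class:`mipalm.search.Complex` objects or any object exposing
    ``members``, ``n_s`` and ``delta_s``.  Output round-trips through
    ``read_complex_catalog(path, has_name=True, n_skip_fields=2)``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# rank\tsize\tdensity_score\tmembers...\n")
        for rank, cx in enumerate(complexes, start=1):
            members = "\t".join(sorted(cx.members))
            fh.write(f"{rank}\t{cx.n_s}\t{cx.delta_s:.6g}\t{members}\n")


def read_annotation_table(path: str | Path, delimiter: str | None = None) -> AnnotationTable:
    """Read a two-column (protein, label) TSV into an annotation table.

    Multi-label proteins accumulate label sets across lines.
    """
    mapping: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split(delimiter)
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
        mapping.setdefault(fields[0], set()).add(fields[1])
    return AnnotationTable(mapping)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph as a two-column tab-delimited edge list (sorted)."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u}\t{v}\n")


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    """Write an annotation table as (protein, label) rows, sorted."""
    with open(path, "w", encoding="utf-8") as fh:
        for protein in sorted(table.mapping):
            for label in sorted(table.mapping[protein]):
                fh.write(f"{protein}\t{label}\n")
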