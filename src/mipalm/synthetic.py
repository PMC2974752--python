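"""Seeded generator of benchmark networks with planted complexes.

Emulates the structure a complex-detection algorithm faces in a real PPI
network: a sparse Erdos-Renyi background with embedded dense subgraphs of
4-15 members (known complexes have a median size below 10 proteins),
attached to the background by a few random edges.  The planted member sets
double as a gold-standard catalog, and each planted complex is also given
a private annotation label (standing in for a GO term or sub-cellular
compartment) on top of uniform noise labels, so the enrichment and
co-localization analyses are exercisable without downloads.

The generator does not attempt degree-distribution realism (no scale-free
background); it provides ground truth, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from mipalm.network_io import AnnotationTable, ComplexCatalog

__all__ = ["SyntheticSpec", "generate"]

_MAX_REDRAWS = 1000


@dataclass
class SyntheticSpec:
    """Parameters of a planted-complex benchmark network.

    Defaults describe an easy recovery regime: 20 planted cliques of 6-10
    proteins in a 500-node background at edge probability 0.005, each
    tethered to the background by 2 random edges.
    """

    n_complexes: int = 20
    size_range: tuple[int, int] = (6, 10)
    intra_density: float = 1.0
    background_nodes: int = 500
    background_edge_prob: float = 0.005
    overlap_fraction: float = 0.0
    attachment_edges: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.intra_density <= self.background_edge_prob:
            raise ValueError("planted complexes must be denser than the background")
        if self.size_range[0] < 4:
            raise ValueError("planted complex size must be at least 4")
        if self.size_range[0] > self.size_range[1]:
            raise ValueError("size_range must be (min, max) with min <= max")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.n_complexes < 1 or self.background_nodes < 1:
            raise ValueError("need at least one complex and one background node")


def _planted_subgraph(
    members: list[str], density: float, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Edges of one planted complex: connected, with at least one triangle.

    Draws Erdos-Renyi edges at ``density`` among the members and redraws
    until the induced subgraph is connected and contains a triangle (a
    triangle-free complex could never seed the search, which would make
    recovery benchmarks vacuous).
    """
    pairs = list(combinations(members, 2))
    for _ in range(_MAX_REDRAWS):
        mask = rng.random(len(pairs)) < density
        edges = [p for p, keep in zip(pairs, mask) if keep]
        sub = nx.Graph(edges)
        if sub.number_of_nodes() == len(members) and nx.is_connected(sub):
            if any(t for t in nx.triangles(sub).values()):
                return edges
    raise RuntimeError(
        f"could not draw a connected, triangle-containing subgraph of "
        f"{len(members)} nodes at density {density}"
    )


def generate(spec: SyntheticSpec) -> tuple[nx.Graph, ComplexCatalog, AnnotationTable]:
    """Generate (network, gold-standard catalog, annotation table).

    Same spec (including seed) produces bit-identical output.  With
    ``overlap_fraction > 0`` the corresponding fraction of planted
    complexes shares one member with the previous complex.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    graph = nx.Graph()
    background = [f"B{i:04d}" for i in range(spec.background_nodes)]
    bg_pairs = list(combinations(background, 2))
    mask = rng.random(len(bg_pairs)) < spec.background_edge_prob
    graph.add_nodes_from(background)
    graph.add_edges_from(p for p, keep in zip(bg_pairs, mask) if keep)

    entries = []
    annotations: dict[str, set[str]] = {}
    prev_members: list[str] = []
    lo, hi = spec.size_range
    for i in range(spec.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        members = [f"C{i:02d}_{j:02d}" for j in range(size)]
        if prev_members and rng.random() < spec.overlap_fraction:
            # Share one member with the previous complex.
            members[0] = prev_members[int(rng.integers(len(prev_members)))]
            members = list(dict.fromkeys(members))
        graph.add_edges_from(_planted_subgraph(members, spec.intra_density, rng))
        for _ in range(spec.attachment_edges):
            u = members[int(rng.integers(len(members)))]
            v = background[int(rng.integers(len(background)))]
            graph.add_edge(u, v)
        entries.append((f"planted_{i:02d}", frozenset(members)))
        label = f"L{i:02d}"
        for p in members:
            annotations.setdefault(p, set()).add(label)
        prev_members = members

    # Uniform noise labels over all nodes, complex members included.
    noise_labels = [f"noise{j}" for j in range(5)]
    for node in sorted(graph.nodes):
        annotations.setdefault(node, set()).add(
            noise_labels[int(rng.integers(len(noise_labels)))]
        )

    return graph, ComplexCatalog(entries), AnnotationTable(annotations)
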