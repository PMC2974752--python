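"""Edge weighting, triangle enumeration, and seed ranking.

Within-complex edges tend to share many neighbors, so each edge {v,w} is
weighted by a topological overlap measure

    O_T(v, w) = A_vw * |Gamma(v, w)| / ((k_v + k_w) / 2)

where Gamma(v, w) is the set of common neighbors and k_v, k_w are degrees
in the full network.  The mean-degree normalization (instead of the
classical min(k_v, k_w)) keeps a low-degree protein sharing three partners
with a 100-interactor hub from scoring as high as two equal low-degree
proteins sharing the same three partners.

Seeds for the greedy search are the triangles of the network, ranked by
the mean of their three edge weights.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import networkx as nx

__all__ = [
    "EdgeWeights",
    "TriangleSeed",
    "topological_overlap",
    "weight_all_edges",
    "enumerate_triangles",
    "rank_seeds",
]


class TriangleSeed(NamedTuple):
    """A triangle {v,w,x} with its seed weight (mean of 3 edge weights)."""

    members: tuple[str, str, str]
    weight: float


class EdgeWeights:
    """Mapping from an unordered node pair to its overlap weight."""

    def __init__(self, items: dict[tuple[str, str], float] | None = None):
        self._map: dict[tuple[str, str], float] = dict(items or {})

    @staticmethod
    def _key(v: str, w: str) -> tuple[str, str]:
        return (v, w) if v <= w else (w, v)

    def __setitem__(self, pair: tuple[str, str], weight: float) -> None:
        self._map[self._key(*pair)] = weight

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self._map[self._key(*pair)]

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


def topological_overlap(
    graph: nx.Graph, v: str, w: str, normalization: str = "mean"
) -> float:
    """Topological overlap weight of the node pair (v, w).

    Returns 0 for non-adjacent pairs.  ``normalization="mean"`` divides the
    common-neighbor count by (k_v + k_w)/2; ``normalization="min"`` gives
    the classical variant (min degree) retained for comparison only.
    """
    if v == w:
        raise ValueError("topological overlap is defined for distinct nodes")
    if v not in graph or w not in graph:
        raise KeyError(f"unknown node in pair ({v!r}, {w!r})")
    if not graph.has_edge(v, w):
        return 0.0
    shared = len(set(graph[v]) & set(graph[w]))
    if normalization == "mean":
        denom = (graph.degree(v) + graph.degree(w)) / 2
    elif normalization == "min":
        denom = min(graph.degree(v), graph.degree(w))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return shared / denom


def weight_all_edges(graph: nx.Graph, normalization: str = "mean") -> EdgeWeights:
    """Weight every edge of the network by its topological overlap."""
    weights = EdgeWeights()
    for v, w in graph.edges():
        weights[v, w] = topological_overlap(graph, v, w, normalization)
    return weights


def enumerate_triangles(graph: nx.Graph) -> list[tuple[str, str, str]]:
    """Enumerate every triangle of the graph exactly once.

    Edge-iterator scheme: for each edge (v, w) of a working copy, every
    common neighbor x closes a triangle {v, w, x}; the edge is then removed
    from the working copy so no triangle is reported twice.  Runs in
    O(k_max * m).  The input graph is not mutated.  Output triples are
    sorted tuples in deterministic (lexicographic) order.
    """
    work = graph.copy()
    triangles: list[tuple[str, str, str]] = []
    for v, w in sorted(tuple(sorted(e)) for e in graph.edges()):
        for x in set(work[v]) & set(work[w]):
            triangles.append(tuple(sorted((v, w, x))))  # type: ignore[arg-type]
        work.remove_edge(v, w)
    triangles.sort()
    return triangles


def rank_seeds(
    triangles: Iterable[tuple[str, str, str]], weights: EdgeWeights
) -> list[TriangleSeed]:
    """Rank triangles by mean edge weight, descending.

    Ties are broken by lexicographic order of the sorted member triple, so
    the seed order is deterministic across runs.
    """
    seeds = []
    for tri in triangles:
        v, w, x = sorted(tri)
        for pair in ((v, w), (v, x), (w, x)):
            if pair not in weights:
                raise KeyError(f"no weight for edge {pair} of triangle {tri}")
        mean_w = (weights[v, w] + weights[v, x] + weights[w, x]) / 3
        seeds.append(TriangleSeed((v, w, x), mean_w))
    seeds.sort(key=lambda s: (-s.weight, s.members))
    return seeds
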