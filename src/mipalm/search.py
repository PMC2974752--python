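"""The miPALM engine: greedy seed expansion, merging, filtering, tuning.

Pipeline (``run_mipalm``):

1. weight every edge by topological overlap and rank all triangles by mean
   edge weight;
2. for each top-ranked seed not already covered by a previous candidate,
   greedily merge the frontier node with the largest local-modularity gain
   dLQ_alpha while that maximum is >= 0 (a strictly negative maximum
   stops the growth);
3. discard candidates that never grew beyond their 3-node seed
   (unpromising seeds);
4. merge any two candidates whose overlap score |S&T|/min(|S|,|T|)
   exceeds 0.5, transitively, highest overlap first;
5. drop merged complexes whose density score delta_s = density * size
   falls below the threshold delta.

The whole pipeline is deterministic: seed ranking, greedy argmax and
merge order all carry explicit lexicographic tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from mipalm.evaluation import evaluate
from mipalm.modularity import SubnetworkState, update_deltas_after_merge
from mipalm.network_io import ComplexCatalog
from mipalm.topology import TriangleSeed, enumerate_triangles, rank_seeds, weight_all_edges

logger = logging.getLogger(__name__)

__all__ = [
    "Complex",
    "PredictionResult",
    "grow_seed",
    "overlap_score",
    "merge_complexes",
    "density_score",
    "run_mipalm",
    "tune_parameters",
]


@dataclass(frozen=True)
class Complex:
    """A finalized predicted complex."""

    members: frozenset[str]
    n_s: int
    m_ss: int
    delta_s: float


@dataclass
class PredictionResult:
    """Output of the full pipeline plus per-stage provenance counts."""

    complexes: list[Complex]
    alpha: float
    delta: float
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.complexes]

    def __len__(self) -> int:
        return len(self.complexes)


def grow_seed(graph: nx.Graph, seed: TriangleSeed, alpha: float) -> SubnetworkState:
    """Expand a triangle seed by greedy local-modularity ascent.

    Repeatedly merges the frontier node v* with the largest gain
    dLQ_alpha(v, S); growth stops when the maximum gain is strictly
    negative (a zero gain still merges) or the frontier is empty.  Argmax
    ties are broken toward the lexicographically smallest node ID.
    """
    members = set(seed.members)
    if len(members) != 3 or not all(
        graph.has_edge(u, v) for u in members for v in members if u < v
    ):
        raise ValueError(f"seed {seed.members} is not a triangle of the network")
    state = SubnetworkState.from_members(graph, members, alpha)
    while state.neighbors:
        best = max(state.delta_cache.values())
        if best < 0:
            break
        v_star = min(v for v, d in state.delta_cache.items() if d == best)
        state = update_deltas_after_merge(state, v_star)
    return state


def overlap_score(s: Iterable[str], t: Iterable[str]) -> float:
    """Overlap score |S & T| / min(|S|, |T|) of two complexes."""
    s, t = set(s), set(t)
    if not s or not t:
        raise ValueError("overlap score undefined for empty sets")
    return len(s & t) / min(len(s), len(t))


def merge_complexes(complexes: Sequence[Iterable[str]]) -> list[frozenset[str]]:
    """Agglomerate complexes whose overlap score exceeds 0.5 (strictly).

    Highest-overlap pairs are unioned first; after each union, scores
    involving the new complex are recomputed before the next decision, so
    the result is a fixed point with no remaining pair above 0.5 and is
    independent of input order.  Ties are broken by smaller combined size,
    then lexicographically on the sorted member tuples.
    """
    sets = [frozenset(c) for c in complexes]
    while True:
        best_key = None
        best_pair = None
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                score = overlap_score(sets[i], sets[j])
                if score <= 0.5:
                    continue
                a, b = sorted((tuple(sorted(sets[i])), tuple(sorted(sets[j]))))
                key = (-score, len(sets[i]) + len(sets[j]), a, b)
                if best_key is None or key < best_key:
                    best_key, best_pair = key, (i, j)
        if best_pair is None:
            return sorted(sets, key=lambda s: tuple(sorted(s)))
        i, j = best_pair
        merged = sets[i] | sets[j]
        sets = [s for k, s in enumerate(sets) if k not in (i, j)] + [merged]


def density_score(graph: nx.Graph, members: Iterable[str]) -> float:
    """Density score delta_s = [m_ss / C(n_s, 2)] * n_s.

    The product of the subnetwork's edge density and its size; equals n_s
    for a clique, and at most n_s in general.
    """
    members = set(members)
    n_s = len(members)
    if n_s < 2:
        raise ValueError("density score undefined for fewer than 2 members")
    m_ss = graph.subgraph(members).number_of_edges()
    return m_ss / (n_s * (n_s - 1) / 2) * n_s


def _is_covered(members: tuple[str, ...], candidates: list[frozenset[str]]) -> bool:
    """A seed is covered iff all three nodes lie inside one prior candidate."""
    tri = set(members)
    return any(tri <= c for c in candidates)


def run_mipalm(
    graph: nx.Graph, alpha: float, delta: float, refine: bool = False
) -> PredictionResult:
    """Run the full complex-prediction pipeline.

    Parameters
    ----------
    graph
        Simple undirected PPI network.
    alpha
        Coarseness parameter in [0, 1] controlling the effective background
        neighborhood of the local-modularity score.
    delta
        Density-score threshold; merged complexes with delta_s < delta are
        deleted (equality keeps).
    refine
        Reserved post-expansion refinement hook; currently a no-op.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta}")

    weights = weight_all_edges(graph)
    triangles = enumerate_triangles(graph)
    if not triangles:
        logger.warning("network contains no triangles; no complexes can be seeded")
        return PredictionResult([], alpha, delta, {"seeds": 0})
    seeds = rank_seeds(triangles, weights)

    candidates: list[frozenset[str]] = []
    n_grown = 0
    n_unpromising = 0
    n_skipped_covered = 0
    for seed in seeds:
        if _is_covered(seed.members, candidates):
            n_skipped_covered += 1
            continue
        state = grow_seed(graph, seed, alpha)
        n_grown += 1
        if state.n_s == 3:  # unpromising seed: never expanded
            n_unpromising += 1
            continue
        if refine:
            pass  # refinement hook: no rule currently defined
        candidates.append(state.members)

    merged = merge_complexes(candidates)

    complexes = []
    n_filtered = 0
    for members in merged:
        d_s = density_score(graph, members)
        if d_s < delta:
            n_filtered += 1
            continue
        m_ss = graph.subgraph(members).number_of_edges()
        complexes.append(Complex(members, len(members), m_ss, d_s))
    complexes.sort(key=lambda c: (-c.delta_s, tuple(sorted(c.members))))

    provenance = {
        "seeds": len(seeds),
        "searches": n_grown,
        "skipped_covered": n_skipped_covered,
        "unpromising": n_unpromising,
        "candidates": len(candidates),
        "after_merge": len(merged),
        "filtered_by_density": n_filtered,
        "final": len(complexes),
    }
    logger.info("pipeline stages: %s", provenance)
    return PredictionResult(complexes, alpha, delta, provenance)


def tune_parameters(
    graph: nx.Graph,
    gold: ComplexCatalog,
    threshold: float = 0.2,
    coarse_step: float = 0.01,
    fine_step: float = 0.001,
    delta_max: float = 3.5,
    delta_step: float = 0.01,
) -> tuple[float, float, float]:
    """Grid-search (alpha, delta) maximizing the F-measure against ``gold``.

    Alpha is scanned over [0, 1] at ``coarse_step``, then refined at
    ``fine_step`` within one coarse step of the optimum; delta is then
    scanned over [0, ``delta_max``] at ``delta_step`` with alpha fixed.
    Since the density filter only thresholds already-computed scores, the
    delta scan reuses a single pipeline run.  Ties resolve to the smallest
    alpha, then the smallest delta.
    """
    if len(gold) == 0:
        raise ValueError("parameter tuning requires a non-empty gold standard")

    def f_at(preds: list[frozenset[str]]) -> float:
        return evaluate(preds, gold, threshold).f_measure

    def scan_alpha(alphas: Iterable[float], best: tuple[float, float]) -> tuple[float, float]:
        best_f, best_a = best
        for a in alphas:
            result = run_mipalm(graph, a, 0.0)
            f = f_at(result.member_sets)
            if f > best_f:
                best_f, best_a = f, a
        return best_f, best_a

    n_coarse = round(1 / coarse_step)
    coarse = [round(i * coarse_step, 10) for i in range(n_coarse + 1)]
    best_f, best_alpha = scan_alpha(coarse, (-1.0, 0.0))
    lo = max(0.0, best_alpha - coarse_step)
    hi = min(1.0, best_alpha + coarse_step)
    n_fine = round((hi - lo) / fine_step)
    fine = [round(lo + i * fine_step, 10) for i in range(n_fine + 1)]
    best_f, best_alpha = scan_alpha(fine, (best_f, best_alpha))

    # Density scores are fixed once alpha is fixed; sweep the threshold.
    base = run_mipalm(graph, best_alpha, 0.0)
    scored = [(c.delta_s, c.members) for c in base.complexes]
    best_delta = 0.0
    best_f_delta = -1.0
    n_delta = round(delta_max / delta_step)
    for i in range(n_delta + 1):
        d = round(i * delta_step, 10)
        preds = [members for d_s, members in scored if d_s >= d]
        f = f_at(preds)
        if f > best_f_delta:
            best_f_delta, best_delta = f, d
    return best_alpha, best_delta, best_f_delta
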