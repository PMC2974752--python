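"""Evaluation of predicted complexes: F-measure, GO enrichment, co-localization.

A prediction and a known complex match when the MCODE-style matching score

    omega = c^2 / (a * b)

reaches a threshold (0.2 by convention), with a and b the two sizes and c
the intersection size.  Precision is the fraction of predictions matching
at least one known complex, recall the fraction of known complexes matched
by at least one prediction; the F-measure is their harmonic mean.

Biological-relevance checks complement the (inherently incomplete) gold
standard: hypergeometric GO-term enrichment with Bonferroni correction,
and a co-localization log-odds score comparing observed intra-complex
edges between co-compartment members to the count expected at the
complex's own connectivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
from scipy.stats import hypergeom

from mipalm.network_io import AnnotationTable, ComplexCatalog

__all__ = [
    "EvaluationReport",
    "NOT_LOCALIZED",
    "matching_score",
    "evaluate",
    "go_enrichment",
    "colocalization_log_odds",
]

#: Sentinel for compartments where the log-odds is undefined or the
#: observed co-localized edge count is zero: compares False against the
#: strict ``> 0`` localization rule.
NOT_LOCALIZED = float("-inf")


@dataclass
class EvaluationReport:
    """Matching-based precision / recall / F-measure summary."""

    precision: float
    recall: float
    f_measure: float
    matched_predictions: list[frozenset[str]]
    matched_known: list[str]
    threshold: float


def matching_score(pred: Iterable[str], known: Iterable[str]) -> float:
    """Matching score omega = c^2 / (a * b); 1 iff the sets are equal."""
    pred, known = set(pred), set(known)
    if not pred or not known:
        raise ValueError("matching score undefined for empty sets")
    c = len(pred & known)
    return c * c / (len(pred) * len(known))


def evaluate(
    preds: Sequence[Iterable[str]],
    gold: ComplexCatalog,
    threshold: float = 0.2,
) -> EvaluationReport:
    """Score predictions against a gold-standard catalog.

    A prediction matches if omega >= threshold against at least one known
    complex, and vice versa; one prediction may match several known
    complexes (counts are of matched entities, not matched pairs).  With no
    predictions, precision is 0 by convention.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"matching threshold must be in (0, 1], got {threshold}")
    if len(gold) == 0:
        raise ValueError("evaluation requires a non-empty gold standard")
    pred_sets = [frozenset(p) for p in preds]
    matched_preds = [
        p for p in pred_sets
        if any(matching_score(p, members) >= threshold for _, members in gold)
    ]
    matched_known = [
        name for name, members in gold
        if any(matching_score(p, members) >= threshold for p in pred_sets)
    ]
    precision = len(matched_preds) / len(pred_sets) if pred_sets else 0.0
    recall = len(matched_known) / len(gold)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EvaluationReport(precision, recall, f, matched_preds, matched_known, threshold)


def go_enrichment(
    complex_members: Iterable[str],
    annotations: AnnotationTable,
    background: Iterable[str],
) -> list[tuple[str, float, float]]:
    """Hypergeometric term enrichment for one complex, Bonferroni-corrected.

    For every term with at least one hit in the complex, the raw p-value is
    the upper tail P(X >= x) of the hypergeometric distribution with
    population N = |background|, K = background proteins carrying the term,
    n = |complex| draws and x observed hits.  The corrected p-value
    multiplies by the number of terms tested for this complex (capped at
    1).  Results are sorted by corrected p, then term.
    """
    members = set(complex_members)
    background = set(background)
    if not members <= background:
        raise ValueError("complex members must be contained in the background set")
    n_pop = len(background)
    n_draw = len(members)

    hits: dict[str, int] = {}
    for p in members:
        for term in annotations.labels_of(p):
            hits[term] = hits.get(term, 0) + 1
    n_tested = len(hits)

    results = []
    for term, x in hits.items():
        k_term = sum(1 for p in background if term in annotations.labels_of(p))
        if x > k_term or n_draw > n_pop:
            raise ValueError(f"inconsistent annotation counts for term {term!r}")
        raw = float(hypergeom.sf(x - 1, n_pop, k_term, n_draw))
        results.append((term, raw, min(1.0, raw * n_tested)))
    results.sort(key=lambda r: (r[2], r[0]))
    return results


def colocalization_log_odds(
    graph: nx.Graph,
    complex_members: Iterable[str],
    annotations: AnnotationTable,
    compartment: str,
) -> float:
    """Log-odds that a complex co-localizes to one sub-cellular compartment.

    Compares m_sk, the number of intra-complex edges whose both endpoints
    localize to compartment k, with the count expected at the complex's own
    connectivity p_s = 2 m_ss / (n_s (n_s - 1)):

        log( m_sk / ( C(n_sk, 2) * p_s ) )

    where n_sk is the number of members localized to k.  The complex is
    declared localized to k iff the score is strictly positive.  When fewer
    than two members carry the compartment, or no co-localized edge is
    observed, returns :data:`NOT_LOCALIZED`.
    """
    members = set(complex_members)
    n_s = len(members)
    if n_s < 2:
        raise ValueError("co-localization needs at least 2 members")
    m_ss = graph.subgraph(members).number_of_edges()
    if m_ss == 0:
        raise ValueError("co-localization undefined for a complex with no internal edges")
    in_k = {p for p in members if compartment in annotations.labels_of(p)}
    n_sk = len(in_k)
    if n_sk < 2:
        return NOT_LOCALIZED
    m_sk = graph.subgraph(in_k).number_of_edges()
    if m_sk == 0:
        return NOT_LOCALIZED
    p_s = 2 * m_ss / (n_s * (n_s - 1))
    expected = n_sk * (n_sk - 1) / 2 * p_s
    return math.log(m_sk / expected)
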