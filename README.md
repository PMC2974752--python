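# mipalm

Protein complex detection in protein–protein interaction (PPI) networks by
**parametric local modularity**, for anyone who has an edge list of physical
interactions and wants candidate complexes — dense, locally coherent
subnetworks — out the other end, together with the tools to judge them
(F-measure against a catalog, GO-term enrichment, co-localization).

## The method

Global (Newman–Girvan) modularity scores a module S of a network with m
edges as

    Q_S = m_SS / m − (d_S / 2m)²

where m_SS is the number of edges inside S and d_S the summed degrees of
its members. Because the expected-connectivity term is computed against the
entire network, Q cannot resolve modules far smaller than the network —
and protein complexes have a median size below 10 proteins. `mipalm`
replaces the fixed denominator with a tunable one:

    LQ_α = m_SS / m − (d_S / (2 m^((α+1)/2)))²,   0 ≤ α ≤ 1

The coarseness parameter α sets the effective background neighborhood (the
edge-coverage ratio is r = m^(α−1)); α = 1 recovers global modularity, and
smaller α penalizes size, favoring small dense modules. The gain from
merging an outside node v into S,

    ΔLQ_α(v, S) = (1/m) · (m_vS − d_v·d_S / (2 m^α)),

drives a greedy search: edges are weighted by a degree-normalized
topological overlap O_T(v,w) = A_vw·|Γ(v,w)| / ((k_v+k_w)/2), triangles are
enumerated and ranked by mean edge weight, and each top-ranked uncovered
triangle is expanded while max_v ΔLQ_α ≥ 0. Gains are maintained
incrementally through a recursion, so each merge costs O(k_v*). Candidates
that never grow beyond their seed are dropped; overlapping candidates
(overlap score |S∩T|/min(|S|,|T|) > 0.5) are merged; survivors are filtered
by the density score δ_s = [m_SS / C(n_s,2)]·n_s ≥ δ.

## Worked example

```python
import networkx as nx
from mipalm import run_mipalm, evaluate
from mipalm.synthetic import SyntheticSpec, generate

graph, gold, annotations = generate(SyntheticSpec(seed=1))
result = run_mipalm(graph, alpha=0.5, delta=2.0)
report = evaluate(result.member_sets, gold, threshold=0.2)
print(len(result), round(report.precision, 3),
      round(report.recall, 3), round(report.f_measure, 3))
```

prints

```
24 0.792 0.95 0.864
```

— on a 666-node benchmark with 20 planted near-cliques of 6–10 proteins in
a sparse background, the pipeline at α = 0.5, δ = 2 returns 24 complexes of
which 79.2% match a planted complex at matching score ω = c²/(a·b) ≥ 0.2,
and 95% of the planted complexes are recovered (F = 0.864).

The same pipeline from a shell:

```
mipalm simulate --out-prefix bench --seed 1
mipalm predict  --network bench.edges.tsv --alpha 0.5 --delta 2.0 --out pred.tsv
mipalm evaluate --pred pred.tsv --gold bench.gold.tsv \
                --network bench.edges.tsv --go bench.annotations.tsv
mipalm tune     --network bench.edges.tsv --gold bench.gold.tsv
```

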