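# Methods

## Model and procedure

`mipalm` treats protein complexes as small, dense, locally coherent
subnetworks of an undirected, unweighted PPI graph G with n nodes and m
edges (self-loops and duplicate edges removed at load time). The pipeline
has three stages.

**Seeding.** Every edge {v,w} is weighted by a topological overlap measure

    O_T(v, w) = A_vw · |Γ(v, w)| / ((k_v + k_w) / 2)

with Γ(v,w) the common neighbors of v and w (v and w themselves excluded)
and k the degree in the full network. Normalizing by the mean degree
rather than the classical min(k_v, k_w) keeps hub edges from scoring as
high as edges between two equally low-degree proteins sharing the same
partners; the min-normalized variant remains available behind the
`normalization="min"` flag for comparison. All triangles are enumerated by
an edge-iterator scheme (for each edge of a working copy, every common
neighbor closes a triangle; the edge is then deleted from the copy), which
emits each triangle exactly once in O(k_max·m). Triangles are ranked by
mean edge weight, ties broken lexicographically on the sorted member
triple. Zero-weight triangles are kept and rank last: they are legitimate
seeds whose edges simply share no further neighbors.

**Greedy expansion.** The quality of a candidate subnetwork S is the
parametric local modularity

    LQ_α = m_SS/m − (d_S / (2 m^((α+1)/2)))²,   0 ≤ α ≤ 1

where m_SS counts edges inside S and d_S sums full-network degrees of its
members (degrees are never recomputed on induced subgraphs: the
configuration-model expectation requires full-network degrees). α tunes
the effective background: the edge-coverage ratio is r = m^(α−1), so α = 1
(r = 1) recovers the single-module term of global modularity and smaller α
inflates the expected-edges penalty, selecting smaller modules. The merge
gain for an outside node v is

    ΔLQ_α(v, S) = (1/m)(m_vS − d_v·d_S/(2 m^α)).

Starting from a seed triangle, the node with the largest gain is merged
while the maximum gain is ≥ 0; growth stops on a strictly negative
maximum (so a zero-gain merge continues — the literal reading of the stop
rule, which also guarantees termination because each merge consumes a
node). Argmax ties resolve to the smallest node ID. After each merge the
frontier gains are updated by the recursion

    ΔLQ_α(v, S∪{v*}) = ΔLQ_α(v, S) + ΔLQ_α(v, {v*})          (v retained)
    ΔLQ_α(v, S∪{v*}) = −d_v·d_S/(2 m^(α+1)) + ΔLQ_α(v, {v*}) (v newly reachable)

(d_S taken before the merge), costing O(k_v*) per merge instead of a full
recomputation; the identity is exact and tested against direct evaluation
to 1e-9 over random merge sequences.

**Assembly.** A seed whose triangle lies entirely inside an
already-collected candidate is skipped (this still permits overlapping
complexes, since partial containment does not suppress a seed). Searches
that never grow past their 3-node seed are discarded as unpromising.
Candidates are then agglomerated: while any pair has overlap score
|S∩T|/min(|S|,|T|) strictly greater than 0.5, the highest-scoring pair is
unioned (ties: smaller combined size, then lexicographic), with scores
recomputed after every union so the result is order-independent. Finally
each merged complex is re-scored on the network by the density score
δ_s = [m_SS/C(n_s,2)]·n_s (recomputed on the union, since filtering
follows merging) and deleted if δ_s < δ (equality keeps).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| α | coarseness of the background neighborhood, dimensionless in [0,1] | tuned; 0.5 in benchmarks | α=1 ≡ global modularity; r = m^(α−1) |
| δ | density-score threshold, in (0, n_s] units of δ_s | tuned; 2.0 in benchmarks | δ_s ≤ n_s always; a clique scores n_s |
| ω | matching-score threshold for evaluation | 0.2 | MCODE convention |
| corrected p | GO-enrichment significance | 0.05 | Bonferroni over terms tested per complex |

`tune_parameters` grid-searches α over [0,1] at step 0.01, refines at step
0.001 within one coarse step of the optimum, then sweeps δ over [0, 3.5]
at step 0.01 with α fixed; because δ only thresholds already-computed
density scores, the δ sweep reuses a single pipeline run. Ties resolve to
the smallest α, then smallest δ.

## Evaluation stack

A prediction matches a known complex when ω = c²/(a·b) ≥ 0.2; precision is
the fraction of predictions matched, recall the fraction of known
complexes matched (matched entities, not matched pairs — one prediction
may match several known complexes), F their harmonic mean. GO enrichment
uses the hypergeometric upper tail P(X ≥ x) with the background restricted
to annotated proteins present in the input network (a conservative choice;
the genome-wide background would only make p-values smaller), Bonferroni
correction dividing by the number of terms actually tested for that
complex. Co-localization compares m_sk, the number of intra-complex edges
whose two endpoints share compartment k, with its expectation
C(n_sk,2)·p_s at the complex's own connectivity p_s = 2m_SS/(n_s(n_s−1));
the complex localizes to k iff log(m_sk/expectation) > 0 strictly. The
edge reading of "co-localized pairs" is deliberate: counting all member
pairs would make the ratio identical for every compartment (always 1/p_s)
and hence uninformative. Compartments with fewer than two localized
members, or no co-localized edge, return the sentinel −inf ("not
localized") rather than an error. A corollary of the strict rule: a
perfect clique all of whose members share a compartment scores exactly 0
and is *not* declared localized — the measure rewards co-localized
connectivity in excess of the complex's own density, which a clique cannot
exhibit.

## Synthetic benchmarks

The generator plants `n_complexes` Erdős–Rényi-dense subgraphs (redrawn
until connected with ≥ 1 triangle, since a triangle-free complex could
never seed the search) inside an Erdős–Rényi background, tethered by
`attachment_edges` random edges each, and emits the planted sets as the
gold standard plus an annotation table giving each complex a private label
over uniform noise labels. Defaults — 20 cliques of 6–10 members, 500
background nodes at edge probability 0.005, 2 attachment edges — define
the "easy regime" used throughout the tests: unambiguous ground truth,
realistic sparsity (~1300 edges on ~660 nodes), trivially small runtime.

What the generator does **not** emulate: scale-free degree distributions,
experimental false positives/negatives, or catalog incompleteness. Passing
the recovery benchmark therefore shows the machinery is correct and the
score behaves as designed on clean planted structure; it does not predict
absolute performance on real interactome data, where α and δ must be
re-tuned against a curated catalog.

## Numerical choices and edge cases

- All modularity arithmetic is double precision; stop and filter
  comparisons are strict exactly as specified (`max Δ < 0` stops, overlap
  `> 0.5` merges, `δ_s < δ` deletes).
- Determinism everywhere: seed ranking, greedy argmax, merge order and
  output ordering all carry lexicographic tie-breaks; the pipeline has no
  randomness, so repeated runs are bit-identical.
- A triangle-free network yields an empty result with a warning, not an
  error. An edgeless network is rejected at load ("empty network").
- The post-expansion refinement hook (`refine=`) is a documented no-op: no
  refinement rule is defined, and the hook exists so one can be added
  without touching the pipeline contract.
- Note on small networks: the ΔLQ_α penalty term scales with 1/m^α, so in
  very small graphs (m ≲ 150) even a perfect clique may fail to grow from
  its seed at mid-range α — the background must carry enough edges for
  within-complex gains to be positive. Benchmarks therefore use several
  hundred background edges.

## Known limitations

- Unweighted networks only; edge confidences are ignored.
- The Muff-style LQ implementation is a comparison utility; its
  neighborhood edge count m_s is taken as edges with at least one endpoint
  in S (edges entirely among first neighbors excluded) — one of two
  defensible readings.
- Greedy expansion finds a local optimum per seed; no backtracking or
  simulated annealing.
- The (α, δ) grid search evaluates the pipeline per α value and is the
  slow path; on large networks use a coarser `coarse_step`.
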