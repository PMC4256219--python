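# Methods

## Scope and model

`gofunsim` computes node-based (information-content based) functional
similarity between proteins annotated with Gene Ontology terms, and
evaluates those measures the way they are benchmarked in practice. The
package deliberately covers the *cross product* of design choices —
four term-IC models, six term-similarity models (two with an XGraSM
variant), four pairwise aggregation strategies and four direct set
measures — because the point of the toolkit is comparing measures, not
advocating one. Path/edge-based measures, GraSM/DCA disjunct-ancestor
variants, HRSS, SSDD and graph-kernel measures are out of scope.

All similarity is within one GO namespace (BP, MF or CC): the three
namespaces are disjoint rooted DAGs and cross-namespace term pairs are
rejected rather than scored 0.

## Ontology handling

OBO 1.2 parsing is delegated to `obonet`; the package then keeps only
`is_a` and `part_of` edges (the relations over which these measures
were defined; the regulates family is counted and dropped, and a
`--relations` flag can widen the set). Obsolete terms are excluded
from the graph but kept for lookup so that "obsolete" and "unknown"
produce different errors; `alt_id`s resolve silently to primary ids.
Each namespace must contain exactly one parentless term (its root) and
the graph must be acyclic; both are hard parse-time errors, and a cycle
error names a member of the cycle.

Ancestor sets are **inclusive** of the query term everywhere. This is
the convention that makes the extended annotation set of Eq.-style
SimGIC ("terms together with their ancestors") a superset of the
direct set, makes the commonality of a term with its own ancestor
contain that ancestor, and gives sim(t,t) = 1 for the normalized
models.

## Annotation corpora

GAF 2.x rows are reduced to (protein, term, evidence, aspect);
qualifier `NOT` rows are dropped, unknown/obsolete terms are dropped
with a logged count (strict mode raises). Frequencies count **distinct
proteins**, not annotation rows: `term_protein_count(t)` is the number
of proteins whose ancestor-closed (true-path propagated) set contains
*t*, so duplicate rows and multiple annotated descendants cannot
inflate a term's frequency. The root's count equals the corpus size
and counts are monotone non-increasing from parent to child; both are
asserted against an independent oracle in the tests. IEA annotations
are kept by default (they dominate real corpora); evidence-code
filtering is available and drops proteins left with no annotations.

## IC models

- **Annotation**: `IC(t) = -ln(count(t)/count(root))` in natural-log
  units. Terms never seen in the corpus have *no* IC; similarity
  queries touching them raise a "term not in corpus" error rather than
  assuming IC 0, because a silent 0 would bias downstream AUC.
- **Zhang**: `IC(t) = -ln(D(t)/D(root))` with `D` the inclusive
  descendant count — a topology-only analogue of the frequency model.
- **Wang**: per target term *t*, S-values satisfy `S_t(t) = 1` and
  `S_t(z) = max_child w(edge) × S_t(child)` walking upward;
  `SV(t) = Σ S_t(z)` over the inclusive ancestor set. Default edge
  weights 0.8 (is_a) and 0.6 (part_of), configurable. Note `SV` is a
  semantic *value*, not a `-ln` quantity: `SV(root) = 1` and every
  non-root term has `SV > 1`.
- **GO-universal**: `ρ(root) = 1`,
  `ρ(t) = max over parents q of ρ(q)/|children(q)|`, `IC = -ln ρ`.
  Because ρ follows the *best* parent, IC is guaranteed to exceed the
  minimum parent IC but not every parent's — a term can sit "above" a
  non-best parent in IC. This is a property of the recursion itself
  and the tests assert exactly that weaker monotonicity (annotation
  and Zhang ICs are monotone along every edge).

The natural logarithm is used throughout; the base only rescales IC
uniformly and every normalized measure is base-invariant.

## Term similarity

The commonality score S is the IC of the most informative common
ancestor (ties broken by the lexicographically smallest term id, for
reproducibility), or, under XGraSM, the mean IC over all informative
(IC > 0) common ancestors — the root never contributes under the
`-ln`-type models. Resnik returns S itself; Lin, Nunivers, Relevance
and Li normalize it as in the README table; the Wang hybrid formula
needs the per-term S-value maps and so requires the Wang IC table, and
has no XGraSM variant (requesting one is an error). When both terms
have IC 0 the normalized models return 0. Relevance and Li were
conceived for annotation IC (where `1 − e^{−S}` is exactly one minus
the MICA's annotation probability); applying them to topology tables
is permitted as a natural extension and flagged in CLI metadata.

## Protein similarity and the measure grid

Pairwise measures build the m×n term-similarity matrix over the
proteins' **direct** annotation sets (the extended sets are available
behind `termset="extended"`, since the convention is not universal)
and aggregate: Avg (grand mean), Max (grand maximum), ABM
(`(Σ row maxima + Σ column maxima)/(m+n)`) and BMA (mean of the two
directional best-match averages). ABM = BMA whenever m = n. Direct-IC
measures always operate on the **extended** sets: SimGIC
(IC-weighted Jaccard), SimDIC (`2I/(S_A+S_B)`), SimUIC
(`I/max(S_A,S_B)`), SimUI (unweighted Jaccard, identical to SimGIC
under an all-ones IC table). An all-zero denominator (every term IC 0)
is defined as similarity 0 with a warning. Unannotated proteins raise
instead of scoring 0.

The grid pairs the annotation family with all eight term models
(Resnik, Lin, Nunivers ± XGraSM, Li, Relevance) × four strategies, and
each topology approach with one term model — Zhang with the Resnik
form on Zhang IC, Wang with its hybrid formula, GO-universal with the
Nunivers form — × four strategies; all four IC families additionally
feed SimGIC/SimDIC/SimUIC, and SimUI stands alone: 32 + 12 + 12 + 1 =
57 labeled configurations. The topology pairings are configurable
defaults (the literature does not fix them uniquely).

Self-similarity: `sim(p,p) = 1` holds by construction for all direct
set measures and for Max/ABM/BMA over Lin, Nunivers or Wang term
similarity. It does **not** hold for Avg over multi-term proteins (the
grand mean includes non-identical term pairs) nor for Relevance, Li or
any XGraSM variant (their correction factors are strictly below 1 even
on a self-pair); `MeasureConfig.self_identity` records which
configurations carry the identity, and the tests assert it exactly
there.

## Evaluation protocols

- **Correlation**: Pearson's r between a measure's scores and a
  reference similarity vector over the same pairs (zero-variance
  input is an error, not NaN).
- **PPI coherence**: positives are interacting pairs; negatives an
  equal-size uniform sample of annotated protein pairs excluding the
  positives and self-pairs. AUC is computed from midranks (the
  fraction of positive–negative pairs ordered correctly, ties ½) —
  exact and threshold-free; the ROC curve at every distinct threshold
  is returned alongside. A useful measure must exceed AUC 0.5.
- **Clustering power**: the Louvain modularity partition of the
  original edge weights is the ground truth; each measure re-weights
  the edges with functional similarity and the graph is re-clustered
  with the same seed. Partitions are compared by entropy-based mutual
  information (natural log), NMI = 2I/(H_g+H_c) — defined as 1 when
  both entropies vanish; the geometric-mean variant I/√(H_g·H_c) is
  available behind `variant="sqrt"` — and the Rand index
  (a+b)/C(N,2), computed from the contingency table. Louvain
  nondeterminism is contracted away by seeding; isolated nodes become
  singletons.

## Synthetic study conditions

All benchmarks are generated, seeded and serializable to OBO/GAF/TSV
so the entire pipeline round-trips through its file formats.

- `fixture_F1`: the frozen worked example (6 terms, 5 proteins) on
  which every documented IC value and similarity score is verified by
  hand to 1e-4.
- `random_dag`: term *i* takes one uniform parent among earlier terms
  plus a second with probability 0.3; edges are part_of with
  probability 0.2. Acyclic and single-rooted by construction.
- `random_annotations`: each protein draws 1 + Poisson(2) distinct
  terms with Zipf(α = 1) popularity over the non-root terms, then
  true-path propagation. Defaults: 150 terms, 200 proteins — the
  ontology is kept larger than the corpus so specific terms annotate
  only a handful of proteins, as in real GO corpora.
- `planted_ppi`: at signal s, a positive pair is (with probability s)
  the next pair from the coherence ranking — pairs sharing at least
  one direct term, ordered by shared-term specificity
  (Σ 1/popularity) times the shared fraction of their direct
  annotation — otherwise a uniform random pair; negatives are uniform
  random non-positive pairs, in equal number (100 + 100 by default).
  The coherence signal is mechanistic (shared direct terms), not any
  of the evaluated similarity measures, so the evaluation is not
  circular. The ranking emulates two features of real interaction
  sets: interacting proteins share *specific* functions, and share
  *most* of their annotation.
- `planted_coexpression`: a planted-partition graph (communities of
  20, within-edge probability 0.9 with weights U(0.7,1), between 0.05
  with U(0.1,0.4)); each community annotates its proteins from a
  distinct block of the ontology, so communities share no direct
  terms.

What passing these benchmarks shows — and does not. The generators
reproduce the *skeleton* of real data: DAG structure with mixed edge
types, Zipf-skewed annotation, coherent positives, modular
co-expression. They do not reproduce annotation depth profiles,
evidence-code mixtures, the shallow-annotation bias of real corpora,
or realistic corpus scale (tens of thousands of proteins), so a
measure's ranking on these benchmarks is a correctness check of the
machinery, not a substitute for benchmarking on real corpora.

## Numerical and design choices

- IC values and scores are kept at double precision internally; TSV
  output rounds to 6 decimals.
- MICA ties and Louvain community ids are deterministically ordered,
  so identical invocations produce byte-identical output.
- Problem sizes in the test-suite benchmarks (200-protein corpora,
  100+100 pairs, 2×20-node graphs, 100-instance oracle sweeps) were
  chosen so the whole suite runs in seconds while leaving the
  stochastic assertions comfortable margins; they are study-condition
  defaults, not tuned per-test constants.
- Benchmarks that require downloading external reference datasets
  (community web services such as CESSM, curated interaction
  databases, historical GOA releases) are intentionally out of scope;
  the correlation protocol itself (`eval corr`, `pearson`) is fully
  implemented and runs on any local reference vector.

## Known limitations

- The Zhang D-value and the GO-universal recursion follow the commonly
  stated descendant-count and max-over-parents forms; both are
  isolated behind the model interface so an alternative reading of
  either method is a one-function change.
- Wang IC precomputes S-value maps for every term, which is quadratic
  in the ancestor-set size; fine at ontology sizes up to a few
  thousand terms, not tuned for the full GO.
- GPAD and GAF 1.0 dialects, OWL ontologies, cross-namespace links and
  GO-slim mapping are unsupported.
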