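# Methods

`plnet` builds *phenotypic-linkage networks*: weighted functional gene
networks in which every edge weight is expressed on a single, biologically
meaningful scale — the semantic similarity of the phenotype annotations of
the two linked genes — and tests gene sets (typically genes hit by de novo
variants in exome studies) for functional clustering with permutation nulls
that control the confounders of such sets. This note documents the model,
its assumptions, the tunable parameters, the synthetic-data generators, and
the numerical choices.

## 1. Semantic similarity of annotations

**Information content.** For a vocabulary annotating genes, each term *a*
carries

IC(*a*) = −log *p*(*a*),

where *p*(*a*) is the proportion of genes annotated with *a* **or any of its
descendant terms** among all genes with at least one annotation. Direct
annotations are stored unpropagated; propagation to ancestors happens when
the IC table is computed. Consequences relied on elsewhere: a root covering
all annotated genes has IC 0, and IC is monotone non-increasing from leaves
to roots. Logarithms are natural by default (`base` option); every
downstream scale — bin medians, rescored link weights, integrated weights —
inherits the choice.

**Term similarity (Resnik with disjunct common ancestors).** The similarity
of two terms is the *average* IC of their disjunct common ancestor set
rather than the IC of the single most informative common ancestor. The
disjunct set is selected greedily: visit common ancestors (a term is its own
ancestor) in decreasing IC order, ties broken lexicographically by term id,
and accept an ancestor iff, for *each* of the two terms, some directed path
from the term to that ancestor avoids every already-accepted ancestor; the
most informative common ancestor is always accepted. In a tree this reduces
to the single lowest common ancestor; in a DAG, independent interpretations
(e.g. the two mid-terms of a diamond) are all retained and averaged.
`plnet.oracles` contains a deliberately slow reference implementation that
enumerates every directed path explicitly; the test suite and the acceptance
experiments verify exact agreement on hundreds of random DAGs. Ancestors
without an IC entry (they annotate no gene) are dropped from the average;
an empty set maps to similarity 0.

**Gene similarity.** Two aggregation rules over the genes' term sets are
provided: `max` (largest term-pair similarity) and `bma` (best-match
average: each term of either set contributes its best match in the other
set; all best matches are pooled with equal weight per term, so unequal set
sizes weigh by term count — a documented, configurable choice). Flat
vocabularies (KEGG/Reactome/InterPro-like, no hierarchy) use direct matches
only: the maximum IC over exactly-shared terms. A gene with no annotation
has an **undefined** (None) similarity, never 0, so unannotated genes can be
excluded from benchmark statistics instead of deflating them.

## 2. Evidence sources

Every source is reduced to a `LinkSet`: unordered gene pairs with one score.

* **Co-expression.** Pearson correlation of two genes' expression profiles
  over the samples in which both are expressed (non-missing and above a
  configurable floor, default 0), requiring at least 10 shared expressed
  samples; the correlation uses exactly those shared samples. Zero-variance
  profiles are skipped and counted.
* **Physical interactions (direct).** Binary interactions carry no score,
  so all pairs from one assay type receive that assay's median benchmark
  similarity over its benchmarked pairs (assays with fewer than 100
  benchmarked pairs are dropped). This median *is* the calibration, so
  these link sets enter integration directly as rescored — running the
  regression machinery on a constant score would be degenerate. One link
  set per assay; a pair seen by two assays keeps both candidate weights
  until integration.
* **Physical interactions (indirect).** Non-interacting genes sharing
  interaction partners get the Jaccard index of their partner sets as a raw
  score. Any monotone shared-partner statistic would serve, because the
  benchmark rescoring recalibrates it; Jaccard is chosen for boundedness.
* **Annotation vocabularies.** Pairwise gene similarity (`max`/`bma`/
  `flat`) over the vocabulary's universe, keeping positive scores. Using
  the benchmark vocabulary itself as evidence is refused unless overridden.
* **Pre-scored lists** (co-citation-like). Read from edge-list TSV;
  duplicate unordered pairs collapse to their maximum; self-pairs are
  dropped with a count. Ortholog transfer (a two-column map) is applied
  before evaluation.

## 3. Benchmarking, inclusion and rescoring

The yardstick is an annotation set whose similarity is trusted to reflect
shared function — in the intended application, mouse knockout phenotype
annotations (`bma` by default, configurable). For one source:

1. restrict to pairs where both genes are benchmarked;
2. sort by raw score, largest first (ties broken by pair id);
3. cut into consecutive bins of 1,000 pairs (configurable); the final
   partial bin is kept in reports but flagged and excluded from fitting;
4. per bin, record the median raw score and the median benchmark
   similarity;
5. **inclusion rule:** Spearman rank correlation across the full bins'
   (score median, similarity median) points, one-sided positive p < 0.05.
   Sources failing the rule never reach integration (enforced; `force`
   exists for diagnostics);
6. **rescoring:** ordinary least squares of bin-median similarity on
   bin-median raw score over the full bins; every pair of the source —
   benchmarked or not — is mapped through the fitted line. Fitted values
   are clamped at zero and zero-weight pairs are dropped, keeping all
   integrated weights positive.

The regressor is the bin-median raw score (the binned curve is what the
evaluation produces; fitting on it is robust to score-scale outliers). Only
a linear map is implemented; the binned curve is the natural extension
point should a monotone non-linear fit ever be needed.

At least two full bins are required; otherwise the source fails with
"insufficient benchmark overlap".

## 4. Integration

Rescored sources share the benchmark scale, so their per-pair weights are
comparable. For each unordered pair, collect one weight per source (that
source's maximum, so duplicated records cannot double-count), sort
decreasing as L₀ ≥ L₁ ≥ …, and combine:

* harmonic kernel (default): WS = L₀ + Σᵢ Lᵢ/(D·i)
* geometric kernel: WS = L₀ + Σᵢ Lᵢ/Dⁱ

with free parameter D ≥ 1, default **D = 5**. The harmonic form follows the
linear index of the rank-down-weighting description; the geometric form is
the classic weighted-sum family alternative and is one config switch away.
D is an input, not optimized here. Properties guaranteed and tested:
WS ≥ L₀, single-source identity, monotonicity in every weight, and source-
order invariance. Top-N thinning (e.g. strongest 100,000 links) is a
reporting-time filter (`top_edges`), never applied during integration.

## 5. The clustering test and its matched nulls

The statistic for a study set is S = Σ WS over all within-set pairs that
are network edges; genes absent from the network contribute nothing (they
are counted as zeros, not dropped — conservative). Significance is
empirical over `n_rand` random sets (default 100,000):

p = (1 + #{S_null ≥ S}) / (1 + n_rand),

the add-one permutation estimator (never exactly 0), with ties counted
against significance. The fold change is S divided by the null median.

Null models:

* **uniform** — size-matched sets drawn without replacement from the
  network's genes (study genes included in the universe);
* **cds** — for each study gene, the k = 100 genes with the same or most
  similar longest-CDS length (query excluded; distance ties broken
  lexicographically); each null set draws one gene per candidate list.
  The universe is the full length table, so study genes missing from the
  network still get matched counterparts — conservative;
* **degree** — candidate lists are degree shells (|degree − target| ≤
  tolerance, default 0), auto-widening to the nearest non-empty shell with
  a warning; genes absent from the network match at degree 0.

Duplicate genes inside a null draw are resolved by redrawing the colliding
positions (bounded rounds); in the rare event duplicates survive, the draw
is accepted with a warning and its statistic computed on the de-duplicated
set. Internally the tester indexes the universe once and evaluates null
statistics on a dense (or, above 6,000 genes, sparse) weight matrix in
vectorized chunks, which is what makes hundreds of replicate tests with
n_rand = 999 cheap.

## 6. Synthetic data: what it emulates, what it does not

* `simulate_ontology` — a layered DAG (depth 4, branching 3 by default)
  with 1–2 parents per term; 2,000 genes in 20 equal modules, each module
  owning one leaf term; genes annotated with their module leaf, two random
  mid-layer terms, occasionally a second module's leaf (p = 0.1) and rarely
  a random leaf (p = 0.02), which stretches the IC spectrum the way
  sparsely annotated deep terms do in real phenotype vocabularies.
* `random_dag_ontology` — unconstrained random DAGs (≤ 30 terms in the
  validation studies) for the oracle comparison.
* `simulate_evidence` — raw score = a·(true similarity) + Gaussian noise
  (sd 0.3 by default) on a random coverage subset (50%), with the scale *a*
  hidden from downstream code; a pure-noise switch generates sources that
  the inclusion rule should reject.
* `simulate_lengths_and_network` — CDS lengths are log-normal with
  location 7.5 and scale 0.8 on the natural-log scale (median ≈ 1.8 kb, a
  plausible CDS scale; only order statistics matter to the tests). With z
  the standardized log length, winsorized at |z| ≤ 2, a pair's edge
  probability is d₀·exp(β/2·(zᵢ+zⱼ) + β/2·zᵢzⱼ) clipped to [0, 1]. The
  additive term couples degree to length; the **interaction term is what
  produces length assortativity** (a purely additive exponent factorizes
  over endpoints, leaving every gene's neighbour-length distribution
  identical, i.e. no assortativity at all). The winsorizing and the
  half-strength exponents keep β = 0.5 in the empirically observed strong-
  confound regime (length assortativity ρ ≈ 0.5–0.6) rather than a
  degenerate one in which a handful of extreme-length genes dominate and
  no finite matching list could control them. Same-module pairs gain edge
  probability 0.2 and their weights are multiplied by the effect size 2.0;
  all other weights are log-normal on the benchmark scale, independent of
  length.
* `simulate_study_genes` — `length_biased_null`: genes drawn ∝ CDS length
  with no functional structure (the chance profile of de novo hits under a
  uniform per-base mutation rate); `planted_module`: a uniform draw from
  one module.

Not emulated: realistic expression dynamics (the expression generator only
provides module-correlated positive values with missing entries, enough to
exercise co-expression scoring), annotation-evidence biases, or any
ascertainment structure beyond CDS length. Passing the synthetic studies
therefore shows that the pipeline's statistics behave as designed under the
stated generative assumptions; it does not certify any particular real data
set.

## 7. Reference experiments and problem sizes

`plnet.experiments` fixes the study conditions used by both the test suite
and `scripts/acceptance.py`:

* oracle agreement: 200 random DAGs (5–30 terms, 3–12 genes), 12 term
  pairs each, exact set equality and similarity agreement to 1e-12;
* inclusion calibration: a 250-gene annotation world; 100 pure-noise and
  100 planted sources, bin size 1,000, α = 0.05;
* rescoring recovery: 100,000 pairs, planted map sim = 0.5·score + 0.2,
  noise sd 0.05;
* bias reproduction/cure: 2,000 genes, β = 0.5, 500 replicate sets of 50
  length-proportional genes, n_rand = 999, both uniform and cds nulls;
* power: 200 replicate 20-gene draws from planted modules, cds null;
* p-value uniformity: 500 uniform study sets, uniform null, KS against
  U(0, 1) (the add-one estimator's p-values live on a grid of 1/(n_rand+1),
  negligible at these sizes);
* integration dominance: four sources with noise sd 0.2–0.8 and coverage
  0.45–0.6, rescored, integrated at D = 5, compared bin-by-bin over the
  leading bins both curves possess.

These sizes make the whole battery run in a couple of minutes while keeping
every binomial margin comfortable; they are the package's reference
conditions, not tuning knobs.

## 8. Known limitations

* The greedy disjunct-ancestor rule is validated against exhaustive path
  enumeration under the same greedy ordering; other published variants of
  the disjunctive-ancestor idea may differ on exotic DAGs.
* Only a linear rescoring map is provided.
* The CDS-matched null assumes the length table covers the analysis
  universe; matching quality degrades at the extreme tail of the length
  distribution if the universe is small.
* Empirical p-values are bounded below by 1/(n_rand + 1); multiple-testing
  correction across many gene sets is the caller's responsibility.
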