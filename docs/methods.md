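# Methods

## Problem and model

The package estimates the percentage of a census tract's population with a
diagnosed chronic respiratory condition (asthma or COPD) from covariates
observable without surveys: the rate at which the tract's search queries
mention illness-related keywords, the tract's land-cover composition, and
its demographic profile. The estimator is a random-forest regression over
a per-tract feature vector, evaluated by k-fold cross-validation against
ground-truth prevalence. Random forests are used because tract-level
features are noisy and outlier-prone and the forest is robust to both;
no alternative learners are in scope.

### Query features

`S_i(k)`, the fraction of tract *i*'s queries whose token set contains
keyword *k*, is the primary signal. Matching is exact token membership,
not substring — substring matching conflates short disease acronyms with
unrelated strings and makes tests nondeterministic in spirit; a substring
mode is deliberately not offered. A query mentioning a keyword several
times counts once: the measure is "share of queries that touch the topic",
not token frequency. Three category sums (symptoms, diseases, medications)
are appended to concentrate sparse per-keyword signals.

### Neighbor smoothing

Each query and land-cover feature is replaced by its unweighted mean over
the *m* nearest tracts by Euclidean centroid distance, self included
(`m = 1` is the identity). Defaults: `m = 8`, applied identically to query
and land-cover features; census features are never smoothed because
demographics are defined strictly within tract boundaries. Centroid
distance is the simplest defensible notion of "closest"; polygon-adjacency
alternatives would change which tracts are neighbors but not the averaging
rule. Distance ties are broken lexicographically by tract id so neighbor
lists are reproducible. Column means are not preserved by smoothing
(neighbor relations are not symmetric); nothing downstream assumes they
are.

The m-sweep diagnostic (`sweep_m`, default grid {1, 4, 8, 16, 32})
reports *training-data* correlation per m. It is kept strictly separate
from model comparison, which always uses held-out cross-validation; the
two numbers answer different questions (how much smoothing helps the fit
vs. how well the model generalizes).

### Keyword selection

A skip-gram word2vec model with negative sampling is trained on the query
corpus (d = 100; window w = 6, a typical query length; 5 epochs;
min_count = 5; 5 negative samples; unigram^0.75 noise distribution;
linearly decaying learning rate from 0.025). The trainer is a compact
numpy implementation: vocabulary ordered by frequency then
lexicographically, input vectors initialized uniform in ±0.5/d, output
vectors at zero, gradient collisions within a batch resolved exactly via
scatter-add. It is deterministic given its seed.

All non-seed unigrams are ranked by cosine similarity to the seed terms
{asthma, copd, smoking}. The aggregation across seeds is max-over-seeds by
default — a term strongly tied to any one illness qualifies — with mean
exposed as an option; ties break lexicographically. Selection takes the
maximal prefix of the ranking whose terms are all labeled disease-related,
stopping at the first negative label. Relevance labels are an explicit
input (in the synthetic setting they come from the generator's known
vocabulary; in real use from human curation) — the package takes no stance
on who judges relevance. A curated medication list is then unioned in
under category "medication"; terms already selected keep their original
category (first assignment wins), so the four categories stay disjoint.

### Land-cover features

Twenty categorical sub-classes (NLCD-style codes) are aggregated to
per-tract area proportions by cell-center containment — the standard
zonal-statistics convention: exact, fast, and unambiguous for cells
straddling boundaries. Proportions over attributed cells sum to 1 per
tract. Three adjacency features capture spatial arrangement at equal area
share: for each focal pixel of a class inside the tract, it qualifies if
at least one 4-neighborhood pixel (von Neumann; 8-neighborhood available)
is of the target class, and the feature is qualifying/focal pixels.
Neighbors may lie outside the tract but not outside the raster. "High
developed" is the highest-intensity developed sub-class; "forest" is the
union of deciduous, evergreen and mixed.

Zero-denominator conventions: a tract with no query events gets 0 for all
query features; a tract with no focal pixels gets 0 for the adjacency
features; a tract with no attributed raster cells gets the region-wide
mean proportions. All three are flagged rather than fatal, keeping the
design matrix complete while surfacing sparsity.

### Estimation and evaluation

Forest defaults follow regression conventions: 500 trees, ⌈p/3⌉ features
per split, minimum leaf 5, fixed seed. The state label enters as a single
integer-coded categorical column (trees split on it directly; one-hot is
an option via the persisted code map). Cross-validation partitions tracts
uniformly at random into 5 folds (sizes within 1); each tract is predicted
exactly once by a forest that never saw its target, and fold bookkeeping
is asserted. Metrics are computed on the pooled out-of-fold vector —
Pearson correlation (Spearman available) and MAE in percentage points —
with per-fold values reported alongside, since pooling vs. per-fold
averaging is a genuine choice and both views are cheap. Importances are
node-purity (impurity-decrease) values averaged over the per-fold forests,
sorted descending with lexicographic tie-breaks.

### Filtering

Before modelling, tracts are excluded (with a ledger recording one reason
each, first match wins) in the order: missing census row, no attributed
land-cover cell, fewer than 50 distinct query users. The privacy floor of
50 distinct users is a boundary: exactly 50 is retained. Completeness
reasons precede the privacy reason so that a tract missing data is never
reported as a privacy exclusion. Retained set plus ledger always partition
the input.

## The synthetic city

The generator produces a study region with the statistical structure the
analysis assumes, at desk scale, in planar kilometre coordinates
(Euclidean distances; synthetic regions are small, so map projection
subtleties are irrelevant).

* **Tracts** — a jittered rectangular tiling: rows of near-equal height,
  each row cut into cells, interior cut positions perturbed by a jitter
  fraction (< 0.5 keeps the tiling valid by construction, so areas sum
  exactly to the region area and polygons are interior-disjoint). The
  region edge defaults to making the mean tract area 2.45 km², and
  populations are log-normal (σ = 0.55) around a median of 3652, matching
  the scale of real urban census tracts. State codes are contiguous
  row-major blocks (default 4 states) so the state feature carries
  learnable baseline offsets.
* **Demographics** — symmetric Dirichlet blocks (age 9, gender 2, race 8;
  concentration 5 gives realistic heterogeneity) and poverty uniform on
  [0.05, 0.35].
* **Land cover** — each class gets a Gaussian-smoothed noise field
  (σ = clumping cells) offset by its log weight; cells take the argmax
  class, giving coherent patches. `clumping = 0` draws cells i.i.d. from
  the weight mixture exactly. The default mixture is urban-leaning.
* **Prevalence** — `clip(base + Σ_f β_f · feature_f + state_offset +
  N(0, noise_sd), 0, 100)` per outcome, with the generating truth returned
  for recovery tests. Defaults: bases 9.783 (asthma) and 6.416 (COPD) —
  the national tract-level averages for these illnesses — noise_sd 1
  percentage point, state offsets N(0, 1.5²). Default effect sizes load
  asthma on poverty (β = 22), dense development (8), deciduous forest (5)
  and under-5 population (10), and COPD on poverty (18), dense development
  (7) and the 65+ age groups (14 each). These were chosen so the
  tract-level prevalence spread (sd ≈ 2 points) and the share of variance
  explainable from covariates match the regime reported for real
  tract-level estimates, whose ground truth is itself largely
  demographics-derived; `base` is an intercept, so regional means sit
  above it when all effects are positive.
* **Queries** — each tract gets `max(1, round(users_per_capita · pop))`
  users (default 0.05); each user issues Poisson(20) queries of 1 +
  Poisson(3) background tokens with Zipf-like frequencies. With
  probability `base_rate · (1 + signal_strength · prevalence/100)`
  (capped at 1; defaults 0.05 and 2) a disease keyword is inserted, drawn
  by category mix then uniformly within category, so the expected keyword
  rate is monotone in prevalence. Disease queries also receive up to two
  extra disease-topic tokens, giving the corpus the co-occurrence
  structure an embedding can exploit. Queries are bags of tokens — the
  pipeline only tests membership and context windows, so grammar would be
  unused structure. Insertion probability uses the mean prevalence across
  outcomes, since both illnesses share one keyword dictionary.
* **Planted-synonym corpus** — a separate, controlled corpus for embedding
  tests: a topic mixture in which half the queries draw tokens from
  {seed terms ∪ planted related terms} and half from background, so
  related terms share contexts with seeds without ever co-occurring being
  required.

The default keyword fixture ships 88 terms in four categories; the count
is cosmetic realism and nothing asserts it. The generator does not model
internet-penetration confounding (users_per_capita is a single knob,
uniform across tracts by default), temporal query dynamics, real
geography, or reverse-IP error (synthetic events carry exact tract
assignments; a point-in-polygon utility covers coordinate inputs). Tests
passing on this generator therefore show the pipeline's correctness and
calibration under its stated assumptions — not that real query data carry
this much signal.

## Numerical and determinism choices

* All randomness flows from explicit integer seeds; the one-stop
  `simulate_city` derives stage sub-seeds from a master seed via
  `SeedSequence`. Identical seeds give byte-identical outputs, and report
  writers emit canonical JSON/CSV so CLI reruns are byte-stable.
* Boundary points in point-to-tract assignment go to the lexicographically
  smallest covering tract id.
* Pearson correlation raises on zero-variance input rather than returning
  NaN; cosine similarity raises on zero vectors. Per-fold correlation may
  be NaN in degenerate folds; pooled metrics never are.
* Proportion invariants are enforced at 1e-9 (block sums, land-cover row
  sums); float-mean comparisons in tests use 1e-12 absolute tolerance.

## Problem sizes

The default experiment scenario is 500 tracts, 4 states, ≈ 90 k users and
≈ 2 M query events; cross-validating one variant-outcome pair takes a few
seconds and the full four-variant experiment a couple of minutes on one
CPU. Embedding tests use 2000-query corpora. These sizes give stable
metrics (null correlations ≈ ±0.05 at n = 500) while keeping every script
and the test suite desk-scale.

## Known limitations

* The stop-at-first-negative selection rule is brittle by design: one
  early mislabeled term truncates the keyword set. This mirrors the
  intended curation workflow; the ranked list is persisted so a curator
  can inspect it.
* Fold assignment is uniform random, not spatially blocked; with
  spatially autocorrelated features, CV estimates are mildly optimistic.
  Spatially blocked CV is a natural extension.
* Impurity-based importances are biased toward high-cardinality features;
  they are reported because "node purity" is the quantity of interest
  here, not as a causal claim.
* The linear generative model for prevalence cannot probe the forest's
  advantage on interactions; it is the minimal structure that makes
  recovery testable.
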