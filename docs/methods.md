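# Methods

## Problem and labels

Genetic redundancy is observed through mutant trios: a paralogous gene pair
with phenotype classes for both single mutants (SM) and the double mutant
(DM). Severity is ordinal on five classes — 0 (none), 1A (conditional), 1B
(cellular/biochemical), 1C (morphological), 2 (lethal) — ranked 0–4. The rank
map adopts the listed order 1A < 1B < 1C; since no labeling decision under the
default definitions compares 1A/1B/1C against each other at equal DM class,
users with a different severity ordering can swap the rule table.

A pair is **nonredundant** iff max(rank(SM₁), rank(SM₂)) ≥ rank(DM); redundant
(RD9) otherwise. Sub-definitions RD1–RD8 tile the redundancy region of the
(max SM rank, DM rank) plane:

| definition | max SM rank | DM class |
|---|---|---|
| RD1–RD4 | 0 | 1A / 1B / 1C / 2 |
| RD6 | 1 | 1B |
| RD7 | 1–2 | 1C |
| RD8 | 1–3 | 2 |

RD5 = RD1∪…∪RD4 ("classic"), RD9 = RD1∪…∪RD8 ("inclusive"). The table is a
YAML-overridable data structure; on load the package verifies that RD1–RD8
cells are pairwise disjoint, lie inside the redundancy region, and cover it
exactly, which guarantees the RD5/RD9 union identities and the RD9/NR
partition (tested by enumerating all 125 class combinations). Because pairs
are unordered, predicates depend only on the maximum SM rank, and labeling is
symmetric under swapping the single mutants. Duplicate pair ids are rejected
at load time rather than silently deduplicated.

## Pair-level feature engineering

Gene-level columns are typed binary, categorical or continuous and tagged with
one of six categories. Aggregation per pair: binary → count ∈ {0,1,2};
categorical token sets → overlap, union, percent overlap (0 when both sets are
empty; stored as a real number, display rounding only); continuous →
absolute difference (signed difference would break pair symmetry), average,
max, min, total, with any missing gene value propagating to all five.

Transform variants: square, log₁₀, reciprocal, and quartile bins for
categorical-summary and continuous aggregations (binary counts skip binning).
Numerical conventions, all frozen on the training pairs and recorded per
column:

* missing values → median imputation after aggregation, before transforms;
* log₁₀ on a column containing 0 → log₁₀(x + δ), δ = the smallest positive
  value in the training column; strictly positive columns use plain log₁₀;
* reciprocal → zeros replaced by the smallest positive training value;
* columns with negative values skip log/reciprocal with a logged warning
  (the column is simply not emitted);
* quartile bins use the empirical 25/50/75% quantiles; boundary ties take the
  lower bin; the edges are frozen so new pairs are binned on the training
  distribution (no leakage).

Transforms are applied after aggregation (matching derived feature names such
as "reciprocal of the difference in lethality score"), and quartile binning is
applied to categorical summaries as well as continuous aggregations. Schemes:
NT emits untransformed aggregations only; MT emits every variant (25 columns
per continuous base feature, 15 per categorical, 4 per binary); BT is resolved
at feature selection, keeping the single highest-importance variant of each
aggregated base feature — the aggregation (max/min/avg/...) stays distinct,
only the transform collapses. An optional PCA step appends the top principal
components of the full matrix as extra features.

## Association statistics

Binary pair counts are dichotomized as presence (≥1) vs absence and tested
with two-sided Fisher's exact tests; the effect size is the cross-product
odds ratio with a 0.5 continuity correction when a cell is zero, and a
degenerate margin yields p = 1 with an undefined odds ratio. Continuous and
categorical-summary columns use the Wilcoxon rank-sum test (normal
approximation with tie correction by default; exact enumeration for small
untied samples), with effect size z/√n where z is recovered from the
two-sided p-value via the standard normal quantile and signed by the
mean-rank shift. Multiple testing is controlled with Benjamini–Hochberg
q-values; the significance default is q < 0.05 (configurable). Definitions
are compared by Spearman correlation of −log₁₀ q over shared features and
Pearson correlation of importance ranks.

The **feature separation score** for misprediction diagnostics is

(Med[NR→RD] − Med[NR→NR]) / (Med[RD→RD] − Med[NR→NR]),

0 when mispredicted nonredundant pairs sit on the correct-nonredundant median
and 1 when they sit on the correct-redundant median; a zero denominator marks
the feature uninformative (NaN), and an empty group is an error since the
score is then undefined.

## Classifier protocol

1. 10% stratified holdout (190:110 input → 19 redundant + 11 nonredundant
   test pairs).
2. 100 balanced replicates: the majority class is down-sampled without
   replacement to the minority size, minority pairs always retained, one
   sub-seed per replicate.
3. Hyperparameter grid search by stratified 10-fold CV on the first ten
   replicates, maximizing mean AUC-ROC; candidate lists are ordered from
   simple to complex so ties resolve toward the simpler model. Default grids:
   SVM C ∈ {10⁻³…10²}; RF trees ∈ {100,500}, depth ∈ {3,5,10,∞}, max features
   ∈ {√p, 0.1p, 0.5p}; GB learning rate ∈ {0.01,0.1,0.3} with the RF
   depth/feature grids.
4. Feature selection: random-forest impurity importance averaged over the
   first ten balanced replicates, or elastic-net |coefficient| at a
   cross-validated penalty (ElasticNetCV, l1 ratio 0.5, on min–max scaled
   features against the 0/1 label). Top-k (default 200) under NT/MT/BT. The
   Model facade clamps k to the candidate pool when the schema is small; the
   bare operation errors instead, so explicit calls cannot silently shrink.
5. Per replicate: min–max scaling fitted inside each training fold, a
   linear-kernel SVM whose decision values are mapped to [0,1] by Platt-style
   sigmoid calibration on internal folds (tree models use their native
   probabilities), out-of-fold scores from the 10-fold scheme, and the
   decision threshold set to the out-of-fold score candidate maximizing F1
   (ties → lowest threshold, making calls monotone-conservative). Features
   with zero variance inside a replicate are dropped for that member only.
6. Evaluation: per-member ROC and precision–recall curves are vertically
   averaged on a fixed 101-point grid (mean ± SD), with areas by trapezoid on
   the averaged curve. Cross-validation performance averages the members'
   out-of-fold curves; external evaluation scores each member on the new data
   and makes binary calls by mean score against the mean member threshold.
   A pooled-prediction alternative (concatenating out-of-fold scores) was the
   other defensible reading; per-member averaging was chosen because the
   reported curves are explicitly averages over model-building iterations.
7. Prediction: redundancy score = mean calibrated member probability,
   call = score ≥ ensemble threshold (mean of member thresholds; a
   per-member-vote alternative gives nearly identical calls but loses the
   continuous score's interpretation).

Feature importance is the ensemble-mean |weight| of the linear SVM on
normalized features (impurity importance for tree models); ranks are dense
with ties broken by feature name for determinism. Collinear copies of a
feature split the weight between them; the sum over copies recovers the
single-copy weight, which is why the BT scheme collapses transform variants
before ranking.

**Cross-definition protocol.** Training under one definition and testing under
another uses: train = train-definition redundant pairs + a random half of the
nonredundant pool; test = the other half of the nonredundant pool + the
test-definition redundant pairs not in the training definition. Disjointness
is asserted after construction.

A single master seed fans out to named sub-seeds (holdout, replicates, grid,
selection, ensemble), so the full pipeline is bit-reproducible and components
are independently reproducible.

## Synthetic benchmark

The generator emulates the statistical shape a redundancy benchmark assembled
from literature phenotypes would have, without any external data:

* 300 pairs at prevalence 190/300 ≈ 0.63, reflecting the literature bias
  toward reporting severe double-mutant phenotypes. The default balance mode
  is stratified-exact (exactly round(πn) redundant latent states) so the
  benchmark composition is reproducible; `balance="binomial"` gives
  independent Bernoulli draws.
* Gene attributes across all six categories: Bernoulli flags, lognormal
  positive traits (expression-like), uniform percent traits
  (methylation-like), GO-like token sets and coexpression-cluster ids.
* Planted effects (defaults): log-odds +2 on a recent-WGD-like flag and a
  reciprocal-best-match flag; 1.5 SD shifts on five continuous features, with
  substitution rates and stress-response breadths lowered and expression
  similarity raised for redundant pairs, mirroring the expected directions;
  cluster co-membership probability 0.6 for redundant pairs. `effect_scale`
  scales all of them (0 = pure null).
* Phenotypes are emitted from trio-type tables conditional on the latent
  state; redundant trio types always have the DM strictly more severe than
  both SMs (the lethal-DM type is weighted at 0.30 so the extreme-redundancy
  subset is well populated at n = 300), nonredundant types never do. With
  emission noise 0 the labels recover the latent states exactly; noise ε
  draws from the wrong table with probability ε.
* Pairs may share genes (as real paralog sets do; shared genes keep the
  feature values of their first pair); a no-sharing flag exists for tests
  requiring independence.

What the generator does **not** emulate: realistic Ks distributions or
GO-graph structure, correlated noise between related features (beyond the
planted collinearity among the five shifted continuous traits), feature
missingness patterns, and the long tail of weakly informative features in
real data. Passing tests therefore demonstrate that the pipeline recovers
planted signal of the stated sizes and is calibrated under the null — not
that real Arabidopsis data would reach any particular accuracy.

## Problem sizes used in tests and the acceptance script

The library defaults follow the full protocol (100 replicates, 10-fold CV,
grid search). Test and acceptance runs use a reduced configuration chosen as
the package's standard small-problem setting: 8 balanced replicates, 5-fold
out-of-fold scoring, fixed linear-SVM C = 1, BT selection at the default
k = 200 clamped to the compact schema's candidate pool (~77 columns). The
data-generating conditions themselves (300 pairs, 190:110 balance, default
planted effect sizes) are never reduced. Null-calibration and
signal-recovery properties are measured over 20 generator seeds in the test
suite and 10 seeds in the acceptance script.

## Known limitations

* The RD6–RD8 keying by double-mutant class is the natural tiling of the
  subtle-redundancy region but other tilings are conceivable; the rule table
  is data, not code, for exactly this reason.
* Random-forest impurity importance is biased toward high-cardinality
  columns, so low-cardinality binary counts can rank below continuous noise
  during selection; the linear-SVM weights downstream do not share this bias.
* The ensemble threshold (mean of member thresholds) is one of several
  defensible aggregations; with heterogeneous members a pooled out-of-fold
  threshold could differ.
* Wilcoxon z recovered from the two-sided p-value loses the distinction
  between one- and two-sided magnitudes at p near 1 (z ≈ 0 there, so the
  effect size is unaffected in practice).
* Scores are Platt-calibrated within balanced replicates; on strongly
  imbalanced application sets the 0–1 score remains a ranking, not a
  population-frequency estimate.
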