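# Methods

This note records the statistical conventions the package implements, the
choices made where the underlying analysis left the design open, what the
synthetic-data generator does and does not emulate, and the numerical
details a maintainer would need.

## Signatures

Fold changes are differences on the log2 scale: for case sample *s* and
gene *g*, `lfc[g] = expr[g, s] − mean over controls of expr[g, ·]`. The
expression inputs are assumed to be already processed and log2-scaled;
probe collapsing, normalization and batch correction are upstream of this
package.

A disease signature is the top `n_per_side` (default 150) genes by
descending fold change (up side) and ascending fold change (down side).
All rankings break ties deterministically, ending in lexicographic gene-id
order; if a tie spans both tails, the down side excludes genes already
taken by the up side, so the two sides are disjoint by construction.
Signature extraction is invariant to monotone transformations of the
fold-change vector.

Cluster-level differential expression is a per-gene two-group linear model:
the pooled-variance t statistic with n1+n2−2 degrees of freedom and a
two-sided p-value. Empirical-Bayes variance moderation is deliberately
not applied: downstream use is rank-based top-150 selection, where
moderation changes little at the sample sizes involved, and the plain
fixed-effects t keeps the statistic transparent and dependency-free.

Cross-cohort combination takes, per gene, the **maximum** of the two
cohorts' p-values (a conservative intersection-style combination) and
requires the effect signs to agree; sign-discordant genes are ineligible
for the combined signature, since a "common" signature gene with opposite
directions in the two cohorts is meaningless for connectivity queries.
Within each direction, genes rank by ascending max-p, ties by descending
mean |effect|, then lexicographically.

The active visit of a patient is the visit with the highest SLEDAI,
retained only when that maximum is strictly greater than 5; ties go to the
earliest qualifying visit.

## Connectivity engine

The scoring engine replaces a remote connectivity service with a local
implementation of the published conventions:

* **Weighted KS enrichment.** Walking down a drug's full gene ranking, a
  signature gene ("hit") advances the running sum by
  |stat|^w / Σ_hits |stat|^w (default weight exponent w = 1) and a miss
  retreats it by 1/(N − |S|). The enrichment score is the running-sum value
  of maximum absolute deviation, signed. Hits with an all-zero statistic
  fall back to uniform weights.
* **WTCS.** (ES_up − ES_down)/2 when the two sides' scores disagree in
  sign, else 0. Queries must cover ≥ 90 % of the signature genes.
* **NCS / tau.** Per drug, scores are divided by the mean |WTCS| of the
  same-sign entries of that drug's reference (touchstone) row; a drug with
  no same-sign reference score gets NCS 0 (logged). tau is the signed
  percentile rank (mid-rank convention) of |NCS| within the drug's
  reference |NCS| distribution, scaled to [−100, 100]. The construction is
  invariant to jointly rescaling a drug's raw scores (queries and
  reference) by any positive constant. The reference panel needs ≥ 20
  queries; synthetic runs score the whole library against 30 random
  signatures.
* **Absolute rank sum.** Within each patient, drugs rank by |tau|
  descending (average ranks on ties); the statistic is the rank sum across
  patients. The null permutes ranks independently within each patient;
  p-values use the add-one estimator (1 + #{null ≤ obs})/(n_perm + 1), so
  they are never zero and the test is slightly conservative. The internals
  of this selection were not published in detail; this permutation
  formulation is this package's own definition.
* **Cluster-level filter.** Drugs with |tau| ≥ 90 (inclusive) for at least
  one cluster are retained.

Scoring uses one profile per drug; collapsing replicate perturbation
profiles (e.g. MODZ) is out of scope.

## Consensus clustering

Each of `n_resamples` (default 1000) resamples draws 80 % of the patients
*and* 80 % of the drugs without replacement, clusters the subsampled
patient profiles by average-linkage hierarchical clustering on
1 − Pearson correlation, and cuts at each k in the candidate range (2–6 by
default, reusing the same resamples across k). consensus(i, j) is the
co-clustering count over the co-sampling count; pairs never co-sampled get
0 (with 1000 resamples at 80 % this is vanishingly rare). Final labels at
each k come from average-linkage clustering of 1 − consensus. The number
of clusters maximizes the delta-area criterion of the consensus CDF:
Δ(2) = A(2), Δ(k) = (A(k) − A(k−1))/A(k−1). Run parameters (resamples,
fraction, seed, k range) are recorded in the result. By default the
pipeline clusters only the drugs surviving rank-sum selection, falling
back to all drugs when fewer than two survive.

Subgroup statistics: NLR = neut % / lymph % at the active visit (patients
with zero lymphocytes are excluded and logged); dNLR is the Pearson
correlation of the per-visit NLR with SLEDAI (≥ 3 usable visits); both are
compared across subgroups by one-way ANOVA.

## MOA algebra

Cluster × MOA coefficients are the raw matrix product of the
clusters × drugs tau matrix with the binary drugs × MOA table, flagged at
|value| ≥ 90 — the convention kept as printed. Because the product sums
tau values, large MOAs accumulate large coefficients (with tens of member
drugs even noise-level scores can sum past 90); `normalize=True` switches
to per-MOA means to remove that size advantage, and is the recommended
setting for libraries with very uneven MOA sizes. The same product
pattern maps binary drug–target tables through target × cell-type
expression. MOA similarity for a query drug reuses the weighted-KS kernel
with drugs as "genes", the locally computed drug–drug WTCS ranking (each
drug's own top/bottom signature scored against all profiles) as the
profile, |similarity| as the weight statistic, and positional permutation
p-values (add-one, significant at p ≤ 0.05); MOAs with < 2 member drugs in
the ranking are skipped.

## Classifier

Features are per-patient Pearson correlations over the visit series:
dNeu = corr(neut %, SLEDAI), dLym = corr(lymph %, SLEDAI),
dNLR = corr(NLR, SLEDAI). Pearson (not Spearman) is used throughout.
Patients need ≥ 3 visits; zero-variance series make a feature undefined
and exclude the patient from fitting, with the reason reported.

Fitting is maximum-likelihood logistic regression (IRLS via
`statsmodels.GLM` with a binomial family). "Repeated k-fold CV" means
`n_iter` (default 1000) independent random partitions into k folds with
the held-out accuracy averaged; the decision cutoff for newly fitted
models is chosen on each training split by Youden's J on the linear
predictor. The best feature set maximizes mean CV accuracy and is refit on
all data. A k-grid stability report (`k_stability`) shows sensitivity to
the fold count, since the published analysis did not state which k (or
whether iterations meant CV repeats or bootstrap resamples) produced the
final model.

The reference model is shipped as fixed constants — intercept 0.3438,
slope 1.9848 on dNeu, cutoff 0.18 on the **linear predictor** (probability
≈ 0.545, not 0.5) — and is never refit; the boundary value itself is
classified lymphocyte-driven. ROC/AUC use the rank (Mann–Whitney)
formulation with midranks for ties.

## Meta-analysis

Per-cohort 2×2 tables (nephritis yes/no × neutrophil-/lymphocyte-driven,
with the neutrophil-driven subgroup as the exposure/numerator) give
OR = ad/bc and SE(log OR) = √(1/a+1/b+1/c+1/d); any zero cell adds 0.5 to
all four cells (Haldane–Anscombe, flagged). Cohorts combine on the log-OR
scale by DerSimonian–Laird: τ² = max(0, (Q − df)/C) from the fixed-effect
Q, weights 1/(SE² + τ²), normal-approximation p. An iterative
Paule–Mandel τ² is available via `method="pm"`. I² = max(0, (Q−df)/Q)·100.
One cohort passes through with a flag; a leave-one-out table mirrors the
published sensitivity check.

## Synthetic cohorts

The generator plants exactly the structure the pipeline is built to
recover, and writes the ground truth next to the data.

* **Clinical.** SLEDAI is an integer random walk in [0, 20] (start 4–12,
  steps ±3, nudged so nearly every patient has an active visit). The
  driving lineage (neutrophils in neutrophil-driven patients, lymphocytes
  in lymphocyte-driven ones) targets corr(cell %, SLEDAI) ≈ 0.7 by setting
  the SLEDAI slope from the target correlation and the noise SD (default
  6 percentage points). The other lineage follows an asymmetric
  compositional coupling: lymphocyte loss shows almost one-for-one in the
  neutrophil share (neut = 90 − lymph + N(0, 8)), while neutrophil
  expansion is buffered before reaching the lymphocyte share
  (lymph = 40 − 0.2·neut + N(0, 14)). The asymmetry is deliberate: it
  makes dNeu the single most informative feature, which is the planted
  condition the classifier-selection tests recover. With the noise set to
  zero the driving correlation is exactly 1. Nephritis is drawn once per
  patient, with the odds multiplied (default ×2) for neutrophil-driven
  patients. Defaults: 20 patients/subgroup for transcriptomic cohorts,
  60/subgroup for clinical-only cohorts (real clinical cohorts are several
  times larger than transcriptomic ones), 3–8 visits.
* **Expression.** Control means ~ N(7, 1) log2 units; each subgroup owns a
  disjoint module with an up-half and a down-half (150 genes each by
  default) shifted by ±2.0 log2 units in matching cases; N(0, 0.4) noise
  everywhere. Modules have both directions so that a reverting drug
  produces opposite-signed enrichment on the two signature sides — a
  one-sided module would zero the WTCS through the sign-mismatch rule.
* **Drug library.** Reverting drugs rank their target subgroup's up-module
  genes at the bottom (statistic ≈ −3) and down-module genes at the top
  (≈ +3) with jitter; inert drugs are random permutations. MOA annotations
  group reverting drugs by target subgroup; their target genes are drawn
  from their module, and the synthetic target × cell-type table expresses
  module-derived targets highly in the matching cell type.
* **Seeding.** One master seed fans out through `SeedSequence.spawn` into
  per-component child seeds (< 2³¹), so any component can be regenerated
  independently; identical seeds give byte-identical outputs.

What the generator does **not** emulate: realistic L1000-style noise and
replicate structure, realistic SLEDAI clinical dynamics beyond the
correlation structure the classifier consumes, missing visits, treatment
effects, or cohort batch differences. Passing recovery tests therefore
demonstrates that the pipeline's machinery is correct and well calibrated,
not that the biological findings would reproduce on real cohorts — the
headline numbers of the real analysis (e.g. a held-out AUC of 0.87 or a
combined nephritis OR of 1.5) depend on the real patient data, which this
package deliberately does not touch.

## Problem sizes and numerical details

The test suite and the acceptance script run the pipeline at desk scale:
2000-gene universes, 60-drug libraries with 8 reverting drugs per
subgroup, 20 patients per subgroup and cohort, 200 consensus resamples,
500 rank-sum permutations, 50 CV repetitions, 10 recovery seeds — sizes at
which every planted property is comfortably recovered while the whole
suite stays fast. Library defaults are larger where the method calls for
it (1000 resamples, 1000 permutations, 1000 CV iterations).

Degenerate inputs are rejected rather than patched: empty gene sets, a
gene set spanning the whole universe (the miss penalty would divide by
zero), groups with fewer than two samples, single-class label vectors,
all-zero 2×2 margins. Permutation p-values use the add-one estimator
everywhere. Floating-point reproducibility: all randomness flows through
`numpy.random.default_rng` with explicit seeds; fixed seeds give
bit-identical results.

## Known limitations

* The cluster × MOA |coefficient| ≥ 90 rule on raw sums favors large MOAs;
  see above for the normalized alternative.
* The absolute-rank-sum null treats patients as exchangeable and
  independent; correlated patients would inflate the type-I error.
* One profile per drug: dose/cell-line/replicate structure is collapsed
  upstream or ignored.
* The classifier assumes visit series long enough for meaningful Pearson
  correlations; with exactly 3 visits the features are noisy, and the CV
  accuracy of competing feature sets can tie on small cohorts.
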