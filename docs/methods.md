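# Methods

## Problem setting

`metaselect` operates at two levels.  At the *base* level, eight
classification algorithm families are fitted to tabular datasets and their
performance recorded.  At the *meta* level, each dataset is summarized by a
vector of 26 characteristic indicators plus a domain field label, and
learners are trained on (metafeature, outcome) pairs to predict which
algorithms suit which kinds of data.  The package implements both levels,
the published knowledge they produced (a 48-formula resource-prediction
bank and a set of domain-conditional applicability rules), and a synthetic
data generator whose knobs map one-to-one onto measurable metafeatures so
that every stage can be validated against planted ground truth.

## Preprocessing

Only two operations are applied, in a fixed order: attributes missing more
than 30% of their values are dropped, then any remaining incomplete rows
are removed.  The attribute rule runs first precisely so that one
badly-collected column cannot wipe out most of the sample under the row
rule.  The 30% boundary is read strictly (a column at exactly 30% missing
is kept) and is configurable.  No imputation is performed: filled-in values
would distort the distributional indicators that the rest of the pipeline
consumes.  The missing-value ratio metafeature `R_missing` is measured on
the data *as loaded*, since after preprocessing it is identically zero.
Accepted missing sentinels in delimited text are the empty field, `?` and
`NA` (configurable).

A dataset is categorized *continuous* if every attribute is continuous,
*discrete* if every attribute is discrete (binary counts as discrete), and
*mixed* otherwise.  Binary is treated as a sub-kind of discrete, so
`R_discrete + R_continuous = 1` and `R_binary ≤ R_discrete`.

## Metafeatures: estimator choices

Entropies are Shannon entropies in bits (base 2) by default; the base is a
parameter and any formula-bank entry referencing an entropy indicator
records the base it assumes.  Continuous attributes are discretized for the
information indicators by equal-width histogram with
`n_bins = max(2, ⌈log₂ N⌉ + 1)` (Sturges' rule), configurable.  Mutual
information is computed from the joint count table as
`H(X) + H(Y) − H(X,Y)`, clamped at zero against round-off.  Under this
plug-in estimator `MME_CV ≤ min(E_C, ME_V)` always holds, so `ENV ≥ 1` and
`NSR ≥ 0`; when `MME_CV = 0` both ratios are stored as `+inf` and flagged.

The published NB rule for mixed datasets carries the threshold
`NSR > −38.7407`, which the nonnegative plug-in estimator can never
violate; the threshold is stored exactly as published and the rule
consequently always fires for NB on mixed data under the default
estimator.  No attempt is made to guess what estimator produced a negative
NSR in the original benchmark.

Statistical indicators are computed per continuous attribute and averaged
arithmetically across the eligible ones: trimmed mean trims 10% from each
tail; the percentile indicator is the 90th percentile with linear
interpolation; variance uses the n−1 denominator; skewness is the biased
g1; kurtosis is non-excess (normal → 3); the dispersion index is
variance/mean, skipping attributes with zero mean.  Attributes containing
non-positive values are excluded from the geometric and harmonic means and
the exclusion is recorded in the vector's `flags`.  All of these trims,
percentiles and conventions are defaults of this package, chosen to match
common numerical-toolbox behaviour; each is a keyword argument.

## Benchmark harness

Base learners are standard scikit-learn estimators with fixed, documented
hyperparameters: LR (lbfgs, max_iter 2000), decision tree with entropy
criterion, RBF SVM, AdaBoost (50 stumps), kNN (k=5), Gaussian NB, random
forest (100 trees), and a single-hidden-layer perceptron (16 units,
max_iter 500).  Discrete attributes are one-hot encoded; continuous
attributes are standardized for the distance/gradient-based learners (LR,
SVM, kNN, BP).  Evaluation uses a stratified 70/30 holdout with a fixed
seed; ranking uses test-partition accuracy as the generalization-relevant
quantity (train accuracy is recorded too).

Resource accounting: fit time is wall-clock seconds; model memory is the
pickle size of the fitted estimator in bytes — chosen because it is exactly
reproducible across runs, unlike RSS sampling.  Both are reported raw and
as log10, since both quantities span orders of magnitude across datasets
and algorithms.  Failures are captured as records with exactly one reason:
`dimension_limit` (one-hot coefficient count over the cap, checked for LR
and BP before fitting), `category_limit` (a discrete attribute with more
levels than the cap, checked for RF), `memory_limit`, `timeout` (post-hoc
wall-clock check after the fit), or `numeric_error`.  The numeric values of
the caps are configurable; the defaults are deliberately generous because
the limits they emulate are platform-specific.

## Labeling and the domain test

Per dataset, completed records are ranked by test accuracy; ties break by
S_least (higher first), then fit time, then a fixed algorithm order — an
invented but documented chain, since ranking ties must resolve
deterministically.  Ranks 1–3 → Y, 4–5 → M, 6–8 and failures → No.  When
fewer than three algorithms complete, all completed ones receive Y.

The domain test cross-tabulates labels (columns Y/M/No) against domains
(rows medical/biology/general) and computes the R×C chi-square in
marginal-product form, which is algebraically identical to Pearson's
Σ(O−E)²/E (property-tested against `scipy.stats.chi2_contingency` on random
tables).  Zero marginals raise rather than silently collapsing categories,
because the statistic divides by them.  The verdict compares against the
upper-α chi-square quantile at (R−1)(C−1) degrees of freedom with α = 0.05;
expected counts below 5 trigger a logged warning, not a correction — no
continuity correction is applied.

## Formula bank

The 48 linear formulas (8 algorithms × 3 dataset categories × 2 targets)
are shipped as a human-readable CSV resource keyed by
(algorithm, category, target) with one row per term; the loader enforces
uniqueness and the 48-count, and the test suite freezes a SHA-256 of the
file so any edit to the transcription is caught.  Evaluation is plain
`intercept + Σ coefficient × metafeature`; referencing a flagged or
non-finite metafeature is an error naming the feature.  Outputs are log10
magnitudes on the original benchmark's hardware and should be compared
across algorithms, not read as absolute predictions.  Rule thresholds
published as percentages are stored as fractions (77.78% → 0.7778) to match
the metafeature scale.

## Meta-learners

**Stepwise.**  A marginal correlation pre-filter keeps features with
|Pearson r| > 0.3 against a real-valued target.  Bidirectional stepwise
least squares then adds, per round, the candidate with the smallest
partial-F p-value if below `p_enter` (0.05) and removes any included
feature whose p-value exceeds `p_remove` (0.10), iterating to a fixed
point; for a single added regressor the partial F equals the squared t, so
the coefficient t-test supplies the p-value.  Candidate scans are
lexicographic, making the search deterministic.  A binary
recommend-or-not target is fitted as a linear probability model by
default; a logistic mode is available behind a flag.  Note the statistical
consequence of α = 0.05 per entry: with five irrelevant candidates,
at least one false entry occurs in roughly a quarter of runs — exact
support recovery is therefore the typical, not the guaranteed, outcome,
and the tests assert accordingly.

**Gain-ratio tree.**  Recursive partitioning maximizes the gain ratio
(information gain over split information).  Numeric features take binary
splits at midpoints between consecutive distinct sorted values, found by a
single cumulative-count sweep per feature; categorical features (the
domain field label) split multiway.  Growth stops at purity or `min_leaf`
(2).  Pruning is the pessimistic error-based scheme: a subtree is replaced
by a leaf when the leaf's upper-confidence-bound error estimate (one-sided
normal approximation at confidence `cf` = 0.25) does not exceed the sum of
its leaves' estimates.  Cross-validation is stratified k-fold (k = 10)
with seeded shuffling, falling back to plain k-fold when k exceeds the
smallest class count (e.g. leave-one-out).

## Synthetic data: what it emulates and what it does not

Continuous attributes are class-conditional equicorrelated Gaussians with
a mean offset (`class_separation`) and optional location shift
(`continuous_offset`, for emulating strictly positive measurements);
discrete attributes mix a class-determined level with a uniform level at
rate `attribute_class_dependence`, which makes attribute–class mutual
information increase monotonically in the knob; class priors are symmetric
Dirichlet draws; missingness is MCAR.  Every knob is checked against its
metafeature (concentration → E_C, dependence → MME_CV, correlation → MAr,
rate → R_missing) in the tests.  Planted-rule meta-datasets sample each
indicator uniformly from documented plausible ranges and label rows by a
threshold predicate, optionally noise-flipped.

What this does *not* emulate: real clinical data's mixed missingness
mechanisms (MAR/MNAR), heavy-tailed and multimodal attribute
distributions, label noise correlated with attributes, and inter-dataset
heterogeneity of attribute semantics.  Passing tests therefore demonstrate
that the estimators and learners are correct and well-calibrated under
controlled conditions, not that the published applicability rules
generalize to any particular clinical dataset.

## Problem sizes and determinism

Default test and example problem sizes (datasets of 100–600 rows,
meta-datasets of 200–400 rows, 20-seed repetitions for recovery claims)
were chosen as the smallest scales at which the estimators' sampling error
is comfortably inside the asserted tolerances.  Every stochastic component
takes an explicit seed; characterization, labeling, formula evaluation and
tree prediction are fully deterministic given their inputs.

## Known limitations

- Resource formulas transfer only as relative magnitudes; absolute times
  and model sizes depend on hardware and library versions.
- The stepwise linear probability model can predict outside [0, 1]; the
  logistic mode avoids this at the cost of occasional separation failures.
- The gain-ratio tree considers axis-aligned splits only.
- The NSR-threshold rule for NB is vacuous under the default entropy
  estimator (see above); it is retained verbatim for fidelity.
- ARFF reading handles numeric and nominal attributes only (no strings or
  dates), via `scipy.io.arff`.
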