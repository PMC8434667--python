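# Methods

This document records the modelling assumptions, parameter choices, and
numerical conventions behind `gaitropy`, and what the synthetic data do
and do not emulate.

## 1. Feature kernels

### Sample entropy and multiscale entropy

* **Definition.** SampEn(m, r) = −ln(A/B) with Chebyshev distance and a
  **strict** `<` tolerance comparison. Templates run over indices
  0 … N−m−1 and pairs are counted once (i < j); self-matches are
  excluded.
* **Tolerance convention.** In the default fractional mode the
  tolerance is r × SD of the **original** series and is held fixed
  across all coarse-graining scales. This makes the MSE profile
  sensitive to how variance redistributes across scales, which is the
  quantity of interest; re-normalising per scale would erase exactly
  that signal. `absolute_r=True` passes the tolerance through
  unchanged for callers who manage it themselves.
* **Coarse-graining.** Scale τ replaces the series by non-overlapping
  block means of length τ; the trailing remainder (N mod τ) is
  discarded, giving ⌊N/τ⌋ points. Scales 1 … 10 are evaluated by
  default with m = 2, r = 0.15.
* **Undefined values.** If A = 0 or B = 0 (e.g. a constant series, or
  too few matches at coarse scales) SampEn is *undefined* and the
  package returns NaN. NaN propagates through MSEM/MSTD/CI, and
  `extract_features` raises a `FeatureError` unless
  `tolerate_undefined=True`. A silent zero would be a qualitatively
  wrong answer (zero means perfect regularity).
* **Summaries.** MSEM = mean of the 10-scale profile, MSTD = its
  standard deviation, CI = its sum.
* **Implementation.** The O(N²) pairwise Chebyshev comparison is
  vectorised as a boolean closeness matrix combined along diagonal
  shifts; it is exactly equal (not approximately) to the naive double
  loop, which the test suite verifies against an independent oracle.

### Permutation entropy

* Ordinal patterns of order D = 4, delay 1 (defaults), counted with a
  **stable** ranking: ties are broken by earlier index = smaller rank,
  so the measure is deterministic and invariant under strictly
  increasing transforms. Entropy is Shannon entropy in **bits**
  (−Σ p log₂ p), bounded by log₂(D!).

### Statistic features

MEAN, STD, MAX, MIN, and zero-crossing rate (ZCR) per axis. ZCR counts
strict sign products (xᵢ·xᵢ₊₁ < 0) divided by N−1; exact zeros inherit
the preceding sign, so `1, 0, 1` does not cross and `1, 0, −1` crosses
once.

### Feature vector

27 features: {MEAN, STD, MAX, MIN, ZCR, MSEM, MSTD, CI, PE} × {ML, V,
AP}, with canonical names such as `CI (ML)`. All tables use this fixed
order.

## 2. Clinical labelling

* TUG: fall risk when time **strictly** exceeds 12.47 s.
* SFBBS: fall risk when the score is **strictly** below 23 points.
* SPMSQ: fall risk at 3 or more errors (inclusive).
* Combined conditions (TUG+BBS, TUG+SPMSQ, BBS+SPMSQ) use the
  **intersection** rule: a subject is at risk only if flagged by both
  constituent tests.

## 3. Synthetic cohort generator

The generator's design goal is a cohort in which the groups differ in
the **temporal structure** of gait variability — the quantity MSE
measures — while amplitude statistics overlap, so that recovering the
signal genuinely requires the entropy features.

Per-axis signal model (units of g, 50 Hz, 30 s):

```
a(t) = offset + Σ_{h=1..3} (0.15/h)·sin(2π·h·1.8·t + φ_h)   gait harmonics
       + 0.4 · band-limited 1/f^β noise (≤ 2 Hz)             gait variability
       + 0.25 · white noise                                   sensor floor
```

* **Group contrast.** The spectral exponent β of the gait-variability
  noise is drawn per subject from N(1.5, 0.2) for healthy subjects and
  N(0.0, 0.2) for fallers (truncated at 0). Healthy gait variability is
  1/f-like and stays complex across scales; faller variability is
  white-like and loses entropy under coarse-graining — so MSEM and CI
  separate the groups. This encodes the "loss of complexity"
  hypothesis; it is an assumption of the generator, not a finding.
* **Band limit (2 Hz).** Confines the group contrast to coarse
  timescales. Without it, lag-1 structure differs between groups and
  the short-range features (ZCR, PE) absorb the signal, making the
  MSE comparison vacuous.
* **Sensor floor (0.25 g white).** Masks residual lag-1 differences
  and keeps SampEn defined at coarse scales. With weaker noise or
  shorter records, scale-8…10 SampEn occasionally has zero template
  matches; at the default 30 s duration the minimum match count
  observed over a large probe of the generator was ≈ 8, comfortably
  defined. The 30 s duration is therefore a deliberate choice tied to
  τ_max = 10 (3000 samples → 300 points at scale 10).
* **Gravity leak.** A per-axis constant offset ~ N(0, 0.1) emulates
  imperfect sensor orientation and gives MEAN a realistic nuisance
  role.
* **Clinical scores.** Drawn from truncated normals straddling the
  cut-offs (e.g. TUG healthy ≈ N(9.5, 1.8) on [4, 12.4], faller ≈
  N(16.5, 2.5) on [13.2, 30]), so labels derived from scores agree
  with the planted groups.
* **Cohort structure.** A latent frailty score ranks subjects; the
  worst-ranked fraction for each test becomes that test's faller set.
  The default cohort has 74 subjects with faller fractions 17/74 (TUG),
  13/74 (SFBBS), and 6/74 (SPMSQ), so the faller sets are nested and
  the combined conditions are non-trivial.

**What the generator does not emulate:** actual TUG phases
(sit-to-stand, turns), stride-to-stride kinematics, sensor drift or
quantisation, missing data, demographic covariates, or any real
relationship between cognition and gait. Absolute AUC values from the
synthetic cohort characterise the pipeline, not older adults.

## 4. Model evaluation

* **Classifier.** `sklearn` random forest, 500 trees by default
  (heavy test fixtures use 200 as a runtime scaling; the estimator is
  otherwise identical).
* **Cross-validation.** 50 folds, stratified where class counts allow;
  folds with a single training class are skipped with a warning.
* **Importance.** Impurity importance averaged over folds. Ranking
  ties are broken by canonical feature order (stable sort), so rankings
  are deterministic.
* **AUC aggregation.** Default is **pooled out-of-fold**: predicted
  probabilities from all folds are pooled and one ROC AUC is computed.
  With 50 folds of a ~74-subject cohort many test folds contain a
  single class and have no per-fold AUC; pooling uses every subject
  exactly once. `auc_aggregation="mean_over_valid_folds"` is available
  for comparison.
* **Subset evaluation.** Feature subsets are re-ordered to the table's
  column order before fitting, so results do not depend on the order a
  subset is supplied in.
* **With/without-MSE comparison.** The "without" arm removes the 9 MSE
  features *before* ranking, then both arms are ranked and evaluated at
  k = 15, 10, 5 on identical folds.

## 5. Statistics

* **Normality.** Lilliefors-corrected KS test by default (parameters
  estimated from the sample); a naive KS variant is available. Fewer
  than 3 samples or zero variance raises `StatsError`.
* **MSE effect.** Paired two-sided t-test on (condition, k) AUC pairs
  by default; Welch's test optional. Identical paired arms are
  degenerate and return (statistic 0, p = 1) by convention rather than
  NaN. Holm correction is provided but not applied by default.

## 6. Determinism and problem sizes

All randomness flows from a single integer seed through
`numpy.random.default_rng`; pipeline outputs are byte-identical for a
fixed seed. The package's reference problem size — used by
`scripts/acceptance.py` and the heavy tests — is a 200-subject cohort
with 200-tree forests, chosen to finish within minutes on one CPU while
leaving the planted-signal recovery far from threshold.

## 7. Limitations

* The synthetic cohort is the only data source; no claims transfer to
  real accelerometry without validation.
* Impurity importance is biased toward high-cardinality features; all
  features here are continuous, which limits but does not remove the
  bias.
* Paired t-tests across (condition, k) pairs treat the pairs as
  exchangeable observations even though conditions share subjects; the
  p-values are descriptive, not confirmatory.
* SampEn at coarse scales on short records has high variance; the NaN
  sentinel surfaces, but cannot fix, that estimation limit.
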