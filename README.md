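# gaitropy

Entropy-based fall-risk screening from wearable accelerometer signals.

`gaitropy` implements a complete, reproducible pipeline for studying
whether **multiscale entropy (MSE)** of trunk acceleration during a
timed walking task improves machine-learning screening of fall risk in
older adults, compared with conventional statistic features alone.

## Scientific problem

Clinical fall-risk screening relies on functional tests — the Timed Up
and Go (TUG, fall risk when the time strictly exceeds 12.47 s), the
short-form Berg Balance Scale (SFBBS, fall risk strictly below
23 points), and the Short Portable Mental Status Questionnaire (SPMSQ,
fall risk at 3 or more errors). A tri-axial accelerometer worn on the
trunk during the TUG records mediolateral (ML), vertical (V), and
anteroposterior (AP) acceleration. The question is whether nonlinear
*complexity* measures of those signals carry screening information
beyond simple amplitude statistics.

The package provides six building blocks:

| module | contents |
|---|---|
| `gaitropy.features` | sample entropy, multiscale entropy profile, complexity index, permutation entropy, zero-crossing rate, and the canonical 27-feature extraction (9 kinds × 3 axes) |
| `gaitropy.labeling` | the clinical cut-off rules and their pairwise combinations (intersection rule) |
| `gaitropy.synthetic_data` | a physically motivated cohort generator in which groups differ in the temporal structure — not the amplitude — of gait variability |
| `gaitropy.model` | 50-fold cross-validated random-forest feature ranking and top-*k* AUC evaluation, with and without the MSE features |
| `gaitropy.stats` | normality (Lilliefors/KS) and paired *t*-tests on the resulting AUC pairs |
| `gaitropy.io_cli` | configuration files, on-disk formats, and the `gaitropy` command line |

## Core measures

Sample entropy of a series of length *N* with embedding dimension
*m* = 2 and tolerance *r* = 0.15 × SD of the original series:

SampEn(m, r, N) = −ln(A / B),

where *B* counts template pairs of length *m* within Chebyshev distance
strictly less than *r*·SD and *A* counts the same pairs still matching
at length *m* + 1. The MSE profile evaluates SampEn on coarse-grained
series (non-overlapping block means) at scale factors τ = 1 … 10, with
the tolerance fixed from the original series. Three MSE summaries are
extracted per axis: the profile mean (MSEM), its standard deviation
(MSTD), and the complexity index (CI, the sum over scales). Permutation
entropy is the Shannon entropy (in bits) of the ordinal-pattern
distribution with order *D* = 4 and delay 1.

When SampEn is undefined (no template matches, e.g. a constant series)
the package returns NaN — never a silent zero — and feature extraction
raises unless explicitly told to tolerate undefined values.

## Worked example

```python
import numpy as np
import gaitropy as g
from gaitropy import synthetic_data as sd

# 1. Entropy kernels on signals with known structure
rng = np.random.default_rng(0)
white = rng.standard_normal(3000)
pink = sd._colored_noise(3000, beta=1.0, rng=rng)
for name, x in [("white", white), ("1/f", pink)]:
    prof = g.mse_profile(x)
    print(f"{name:>5}: SampEn(scale 1) = {prof[0]:.3f}, "
          f"SampEn(scale 10) = {prof[-1]:.3f}, CI = {g.complexity_index(prof):.2f}")

# 2. Small synthetic screening study
spec = sd.CohortSpec(n_subjects=60, seed=0)
records = sd.simulate_cohort(spec)
features = g.extract_feature_table({r.subject_id: r.recording for r in records})
labels = g.label_table(sd.cohort_scores_table(records))
print(f"\ncohort: {features.shape[0]} subjects x {features.shape[1]} features, "
      f"{int(labels['TUG'].sum())} TUG fallers")

config = g.CvConfig(n_folds=10, rf_n_trees=100, seed=0)
cmp = g.compare_with_without_mse(features, labels["TUG"].to_numpy(),
                                 config, k_list=(10, 5))
print("top 5 features:", ", ".join(cmp["with"]["importance"].ranking[:5]))
for k in (10, 5):
    w = cmp["with"]["results"][k].mean_auc
    wo = cmp["without"]["results"][k].mean_auc
    print(f"top-{k:>2}: AUC with MSE = {w:.3f}, without MSE = {wo:.3f}")
```

Output (verbatim):

```
white: SampEn(scale 1) = 2.498, SampEn(scale 10) = 1.352, CI = 17.08
  1/f: SampEn(scale 1) = 1.997, SampEn(scale 10) = 1.760, CI = 19.06

cohort: 60 subjects x 27 features, 14 TUG fallers
top 5 features: MSEM (V), CI (V), MSEM (AP), PE (ML), CI (ML)
top-10: AUC with MSE = 1.000, without MSE = 0.964
top- 5: AUC with MSE = 1.000, without MSE = 0.964
```

White noise loses entropy under coarse-graining while 1/f noise stays
complex at every scale (higher CI) — the structural difference the
synthetic cohort plants between groups — and the model with MSE
features separates the groups better than the model without them.

## Command line

```bash
gaitropy run --config config.yaml --out results/   # full pipeline
gaitropy simulate / extract / label / train / compare  # individual stages
```

Exit codes: 0 success, 2 configuration error, 3 data error. With a
fixed seed the pipeline output is byte-identical across runs.

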