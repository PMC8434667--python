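"""Normality checks and significance tests for the with/without-MSE comparison.

The AUC samples produced by the cross-validated evaluations are first
checked for normality with a Kolmogorov-Smirnov-type test and the
with-MSE vs. without-MSE arms are then compared with a t-test.

Because the normal parameters are estimated from the same sample, the
default normality test applies the Lilliefors correction; a naive KS
test against the fitted normal is available for comparison.  The t-test
defaults to paired (the two arms share folds/conditions), with Welch's
unpaired test as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors


class StatsError(ValueError):
    """Raised for degenerate statistical inputs."""


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str


def ks_normality(samples, corrected: bool = True) -> TestResult:
    """KS test of normality with mean/SD estimated from the sample.

    With ``corrected=True`` (default) the Lilliefors correction accounts
    for the estimated parameters; otherwise a naive one-sample KS test
    against Normal(mean, SD) is run.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise StatsError(f"need at least 3 samples, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise StatsError("zero-variance sample: normality test is degenerate")
    if corrected:
        stat, p = lilliefors(x, dist="norm")
        return TestResult(float(stat), float(p), "lilliefors")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(float(stat), float(p), "ks_estimated_params")


def mse_effect_t_test(auc_with, auc_without,
                      paired: bool = True) -> TestResult:
    """Two-sided t-test comparing AUCs with vs. without MSE features.

    Paired by condition/fold by default; Welch's unequal-variance test
    when ``paired=False``.  Identical paired arms (all differences zero)
    are degenerate and return statistic 0, p-value 1 by convention.
    """
    a = np.asarray(auc_with, dtype=float)
    b = np.asarray(auc_without, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("need at least 2 observations per arm")
    if paired:
        if a.size != b.size:
            raise StatsError("paired test requires equal-length arms")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0) and np.allclose(diffs.mean(), 0):
            return TestResult(0.0, 1.0, "paired_t_degenerate")
        stat, p = sps.ttest_rel(a, b)
        return TestResult(float(stat), float(p), "paired_t")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(stat), float(p), "welch_t")


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in the pipeline)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running_max)
    return adjusted
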