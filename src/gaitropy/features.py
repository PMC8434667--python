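"""Signal features for unsegmented tri-axial TUG accelerometry.

Implements the 27-feature set used for fall-risk screening: per axis
(mediolateral ML, vertical V, anterior-posterior AP) the five statistic
features (MEAN, STD, MAX, MIN, ZCR), three multiscale-entropy features
(MSEM, MSTD, CI) and permutation entropy (PE).  All features are computed
from the raw acceleration signal; no filtering, segmentation or gravity
removal is applied.

Sample entropy uses natural log; permutation entropy uses log2 (bits).
An undefined sample entropy (no template matches, or zero tolerance) is
represented by NaN and propagates through MSEM/MSTD/CI rather than being
silently replaced by zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AXES = ("ML", "V", "AP")

#: Canonical feature order: statistic block, MSE block, PE block, each per axis.
FEATURE_KINDS = ("MEAN", "STD", "MAX", "MIN", "ZCR", "MSEM", "MSTD", "CI", "PE")
FEATURE_NAMES = tuple(f"{kind} ({axis})" for kind in FEATURE_KINDS for axis in AXES)
MSE_FEATURE_NAMES = tuple(n for n in FEATURE_NAMES
                          if n.split(" ")[0] in ("MSEM", "MSTD", "CI"))

UNDEFINED = float("nan")


class FeatureError(ValueError):
    """Raised for invalid inputs to feature computations."""


@dataclass(frozen=True)
class MseParams:
    """Multiscale-entropy parameters.

    m : template length for sample entropy (default 2).
    r : tolerance as a fraction of the SD of the original series
        (default 0.15), held fixed across scales.
    tau_max : largest coarse-graining scale factor (default 10).
    """

    m: int = 2
    r: float = 0.15
    tau_max: int = 10

    def __post_init__(self) -> None:
        if self.m < 1:
            raise FeatureError(f"m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise FeatureError(f"r must be > 0, got {self.r}")
        if self.tau_max < 1:
            raise FeatureError(f"tau_max must be >= 1, got {self.tau_max}")


@dataclass(frozen=True)
class PeParams:
    """Permutation-entropy parameters: embedding dimension D and delay."""

    D: int = 4
    delay: int = 1

    def __post_init__(self) -> None:
        if self.D < 2:
            raise FeatureError(f"embedding dimension must be >= 2, got {self.D}")
        if self.delay < 1:
            raise FeatureError(f"delay must be >= 1, got {self.delay}")


@dataclass
class Recording:
    """One subject's tri-axial acceleration recording.

    axes maps axis name (ML, V, AP) to a 1-D float array in g-units; all
    three series have equal length >= 2 and contain only finite values.
    """

    axes: Mapping[str, np.ndarray]
    sampling_rate: float

    def __post_init__(self) -> None:
        if set(self.axes) != set(AXES):
            raise FeatureError(f"expected axes {AXES}, got {tuple(self.axes)}")
        arrays = {k: np.asarray(v, dtype=float) for k, v in self.axes.items()}
        lengths = {a.size for a in arrays.values()}
        if len(lengths) != 1:
            raise FeatureError("all axes must have equal length")
        n = lengths.pop()
        if n < 2:
            raise FeatureError(f"recording too short (length {n})")
        for name, a in arrays.items():
            if not np.all(np.isfinite(a)):
                raise FeatureError(f"non-finite values in axis {name}")
        if self.sampling_rate <= 0:
            raise FeatureError("sampling_rate must be positive")
        self.axes = {k: arrays[k] for k in AXES}

    @property
    def n_samples(self) -> int:
        return next(iter(self.axes.values())).size


@dataclass
class FeatureVector:
    """The 27 named features for one recording, plus parameter provenance."""

    values: dict[str, float]
    mse_params: MseParams
    pe_params: PeParams

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_NAMES:
            raise FeatureError("feature names/order must match the canonical 27")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, dtype=float)


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block average of `series` at scale factor `tau`.

    Output element j is the mean of input points (j-1)*tau .. j*tau - 1;
    trailing points that do not fill a block are discarded, so the output
    has length floor(N / tau).
    """
    x = np.asarray(series, dtype=float)
    if tau < 1:
        raise FeatureError(f"scale factor must be >= 1, got {tau}")
    n_blocks = x.size // tau
    if n_blocks == 0:
        raise FeatureError(
            f"series of length {x.size} too short for scale factor {tau}")
    if tau == 1:
        return x.copy()
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def _template_match_counts(x: np.ndarray, m: int, tol: float) -> tuple[int, int]:
    """Count template pairs within Chebyshev tolerance `tol` (strict <).

    Both lengths m and m+1 use templates starting at indices 0 .. N-m-1
    (so every length-m template has a length-(m+1) extension), and pairs
    are counted over i < j, self-matches excluded.  Returns (A, B): the
    (m+1)-match and m-match counts.

    A Chebyshev match of templates i, j over length L is the AND of the
    pointwise matches |x[i+k] - x[j+k]| < tol for k = 0..L-1, so both
    counts come from diagonal-shifted slices of one pointwise match
    matrix (built in row chunks to bound memory).
    """
    n = x.size
    nt = n - m
    close = np.empty((n, n), dtype=bool)
    chunk = max(1, int(2**24 // n))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        close[start:stop] = np.abs(x[start:stop, None] - x[None, :]) < tol
    match = close[:nt, :nt].copy()
    for k in range(1, m):
        match &= close[k:k + nt, k:k + nt]
    upper = np.triu(np.ones((nt, nt), dtype=bool), k=1)
    b_count = int(np.count_nonzero(match & upper))
    match &= close[m:m + nt, m:m + nt]
    a_count = int(np.count_nonzero(match & upper))
    return a_count, b_count


def sample_entropy(series: np.ndarray, m: int = 2, r: float = 0.15,
                   absolute_r: bool = False) -> float:
    """Sample entropy SampEn(m, r) of a series with Chebyshev distance.

    Returns -log(A/B) where B counts pairs of length-m templates within
    tolerance and A the same for length-(m+1) templates.  By default the
    tolerance is r * SD(series) (population SD); with ``absolute_r=True``
    r is used as an absolute amplitude.  Returns NaN (the undefined
    sentinel) when A or B is zero, or when the tolerance is zero.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= m + 1:
        raise FeatureError(
            f"series length {x.size} too short for m={m} (need > m+1)")
    if absolute_r:
        # a zero absolute tolerance arises from a constant source series
        # (r * SD = 0): that is the undefined case, not a usage error
        if r <= 0:
            return UNDEFINED
    elif r <= 0:
        raise FeatureError(f"tolerance must be > 0, got {r}")
    tol = r if absolute_r else r * float(np.std(x))
    if tol <= 0:  # constant series in fraction-of-SD mode
        return UNDEFINED
    a, b = _template_match_counts(x, m, tol)
    if a == 0 or b == 0:
        return UNDEFINED
    return -math.log(a / b) + 0.0  # +0.0 avoids -0.0 when A == B


def mse_profile(series: np.ndarray, params: MseParams = MseParams(),
                absolute_r: bool = False) -> np.ndarray:
    """Sample entropy of the coarse-grained series at scales 1..tau_max.

    The tolerance is fixed at r * SD of the ORIGINAL series for every
    scale (the convention that makes white-noise entropy decay with
    scale while 1/f-noise entropy stays flat).
    """
    x = np.asarray(series, dtype=float)
    tol = params.r if absolute_r else params.r * float(np.std(x))
    profile = np.empty(params.tau_max, dtype=float)
    for tau in range(1, params.tau_max + 1):
        grained = coarse_grain(x, tau)
        if grained.size <= params.m + 1:
            raise FeatureError(
                f"coarse-grained series too short at scale {tau} "
                f"(length {grained.size}, need > {params.m + 1})")
        profile[tau - 1] = sample_entropy(grained, params.m, tol,
                                          absolute_r=True)
    return profile


def complexity_index(profile: Sequence[float]) -> float:
    """Sum of the per-scale sample entropies (NaN propagates)."""
    p = np.asarray(profile, dtype=float)
    if p.size == 0:
        raise FeatureError("empty MSE profile")
    return float(np.sum(p))


def permutation_entropy(series: np.ndarray,
                        params: PeParams = PeParams()) -> float:
    """Permutation entropy in bits: Shannon entropy of ordinal patterns.

    Embeds the series into vectors of dimension D with the given delay,
    maps each vector to the permutation that sorts it (ties broken by
    earlier-index-is-smaller, i.e. stable sort) and returns
    -sum(p_i log2 p_i) over pattern frequencies.  Value lies in
    [0, log2(D!)].
    """
    x = np.asarray(series, dtype=float)
    D, delay = params.D, params.delay
    min_len = (D - 1) * delay + 1
    if x.size < min_len:
        raise FeatureError(
            f"series length {x.size} below minimum {min_len} for "
            f"D={D}, delay={delay}")
    n_vec = x.size - (D - 1) * delay
    emb = x[np.arange(n_vec)[:, None] + delay * np.arange(D)[None, :]]
    # stable argsort: equal values keep index order, so the earlier index
    # receives the smaller rank
    patterns = np.argsort(emb, axis=1, kind="stable")
    codes = patterns @ (D ** np.arange(D))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / n_vec
    return float(-np.sum(p * np.log2(p)) + 0.0)


def zero_crossing_rate(series: np.ndarray) -> float:
    """Fraction of consecutive sample pairs with a strict sign change.

    Exact zeros inherit the preceding sign (no double counting); leading
    zeros carry no sign and cannot produce a crossing.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise FeatureError("need at least 2 samples for zero-crossing rate")
    s = np.sign(x)
    # forward-fill zeros with the previous sign
    nz = s != 0
    idx = np.where(nz, np.arange(s.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.clip(idx, 0, None)], 0.0)
    crossings = int(np.count_nonzero(filled[:-1] * filled[1:] < 0))
    return crossings / (x.size - 1)


def extract_features(recording: Recording,
                     mse_params: MseParams = MseParams(),
                     pe_params: PeParams = PeParams(),
                     tolerate_undefined: bool = False) -> FeatureVector:
    """Compute the canonical 27-feature vector from a raw recording.

    Per axis: MEAN, STD (population), MAX, MIN, ZCR, MSEM (mean of the
    MSE profile), MSTD (SD of the profile), CI (its sum), PE.  If any
    sample entropy is undefined, the affected MSE features are NaN and
    extraction raises unless ``tolerate_undefined`` is set.
    """
    per_axis: dict[str, dict[str, float]] = {}
    for axis in AXES:
        x = recording.axes[axis]
        profile = mse_profile(x, mse_params)
        feats = {
            "MEAN": float(np.mean(x)),
            "STD": float(np.std(x)),
            "MAX": float(np.max(x)),
            "MIN": float(np.min(x)),
            "ZCR": zero_crossing_rate(x),
            "MSEM": float(np.mean(profile)),
            "MSTD": float(np.std(profile)),
            "CI": complexity_index(profile),
            "PE": permutation_entropy(x, pe_params),
        }
        if np.isnan(profile).any() and not tolerate_undefined:
            raise FeatureError(
                f"undefined sample entropy on axis {axis}; "
                "pass tolerate_undefined=True to keep NaN features")
        per_axis[axis] = feats
    values = {f"{kind} ({axis})": per_axis[axis][kind]
              for kind in FEATURE_KINDS for axis in AXES}
    return FeatureVector(values=values, mse_params=mse_params,
                         pe_params=pe_params)


def extract_feature_table(recordings: Mapping[str, Recording],
                          mse_params: MseParams = MseParams(),
                          pe_params: PeParams = PeParams(),
                          tolerate_undefined: bool = False) -> pd.DataFrame:
    """Feature vectors for many recordings as a DataFrame.

    Rows are indexed by subject id (index name ``subject_id``); columns
    are the 27 canonical feature names in order.
    """
    rows = {}
    for subject_id, rec in recordings.items():
        fv = extract_features(rec, mse_params, pe_params,
                              tolerate_undefined=tolerate_undefined)
        rows[subject_id] = fv.values
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(FEATURE_NAMES))
    table.index.name = "subject_id"
    return table
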