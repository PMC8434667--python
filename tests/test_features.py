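"""Unit and property tests for the signal-feature kernels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import gaitropy as g
from gaitropy.features import (
    AXES,
    FEATURE_NAMES,
    FeatureError,
    MseParams,
    PeParams,
    Recording,
)

from oracles import brute_force_pe, brute_force_sampen

finite_series = hnp.arrays(
    dtype=float,
    shape=st.integers(5, 60),
    elements=st.floats(-100, 100, allow_nan=False, width=32),
)


class TestCoarseGrain:
    def test_identity_at_scale_one(self, rng):
        x = rng.standard_normal(37)
        np.testing.assert_array_equal(g.coarse_grain(x, 1), x)

    def test_block_means(self):
        np.testing.assert_allclose(
            g.coarse_grain([1, 2, 3, 4, 5, 6], 2), [1.5, 3.5, 5.5])

    def test_trailing_remainder_discarded(self, rng):
        assert g.coarse_grain(rng.standard_normal(101), 10).size == 10

    @given(finite_series, st.integers(1, 7))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_length_property(self, x, tau):
        if x.size >= tau:
            assert g.coarse_grain(x, tau).size == x.size // tau

    def test_too_large_scale_errors(self):
        with pytest.raises(FeatureError):
            g.coarse_grain([1.0, 2.0], 3)


class TestSampleEntropy:
    def test_periodic_series_is_zero(self):
        x = np.tile([0.0, 1.0], 50)
        assert g.sample_entropy(x, m=2, r=0.2, absolute_r=True) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 201))
            x = rng.standard_normal(n)
            m = int(rng.integers(1, 4))
            fast = g.sample_entropy(x, m=m, r=0.2)
            slow = brute_force_sampen(x, m, 0.2 * np.std(x))
            if math.isnan(slow):
                assert math.isnan(fast)
            else:
                assert fast == slow

    def test_white_noise_entropy_decays_with_scale(self, rng):
        wins = 0
        for _ in range(50):
            x = rng.standard_normal(5000)
            tol = 0.15 * np.std(x)
            s1 = g.sample_entropy(x, 2, tol, absolute_r=True)
            s5 = g.sample_entropy(g.coarse_grain(x, 5), 2, tol,
                                  absolute_r=True)
            wins += s1 > s5
        # one-sided sign test at alpha far below 1e-6
        assert wins >= 45

    def test_constant_series_undefined(self):
        assert math.isnan(g.sample_entropy(np.ones(50), m=2, r=0.15))

    def test_too_short_series_errors(self):
        with pytest.raises(FeatureError):
            g.sample_entropy([1.0, 2.0, 3.0], m=2, r=0.2)

    def test_scale_invariance_in_fraction_mode(self, rng):
        x = rng.standard_normal(300)
        assert g.sample_entropy(x, 2, 0.2) == g.sample_entropy(7.3 * x, 2, 0.2)


class TestMseProfile:
    def test_single_scale_consistency(self, rng):
        x = rng.standard_normal(200)
        prof = g.mse_profile(x, MseParams(tau_max=1))
        assert prof.size == 1
        assert prof[0] == g.sample_entropy(x, 2, 0.15)

    def test_default_profile_has_ten_scales(self, rng):
        assert g.mse_profile(rng.standard_normal(500)).size == 10

    def test_sinusoid_below_white_noise_at_scale_one(self, rng):
        t = np.arange(5000)
        sine = np.sin(2 * np.pi * t / 40)
        noise = rng.standard_normal(5000)
        prof_sine = g.mse_profile(sine)
        assert np.all(prof_sine < g.sample_entropy(noise, 2, 0.15))

    def test_too_short_series_names_offending_scale(self):
        with pytest.raises(FeatureError, match="scale"):
            g.mse_profile(np.random.default_rng(0).standard_normal(35),
                          MseParams(tau_max=10))


class TestComplexityIndex:
    def test_direct_sums(self):
        assert g.complexity_index([0, 0, 0]) == 0
        assert g.complexity_index([0.5, 0.4, 0.3]) == pytest.approx(1.2)

    def test_equals_mean_times_scales(self, rng):
        prof = g.mse_profile(rng.standard_normal(400))
        assert g.complexity_index(prof) == pytest.approx(
            np.mean(prof) * prof.size, abs=1e-12)

    def test_undefined_propagates(self):
        assert math.isnan(g.complexity_index([0.5, float("nan")]))


class TestPermutationEntropy:
    def test_monotone_series_is_zero(self):
        assert g.permutation_entropy(np.arange(1.0, 11.0),
                                     PeParams(D=3, delay=1)) == 0.0

    def test_worked_pair_example(self):
        x = np.array([4, 7, 9, 10, 6, 11, 3], dtype=float)
        expected = -(4 / 6) * math.log2(4 / 6) - (2 / 6) * math.log2(2 / 6)
        assert g.permutation_entropy(x, PeParams(D=2, delay=1)) == \
            pytest.approx(expected)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 51))
            x = np.round(rng.standard_normal(n), 1)  # induce ties
            D = int(rng.integers(2, 5))
            delay = int(rng.integers(1, 3))
            if n < (D - 1) * delay + 1:
                continue
            assert g.permutation_entropy(x, PeParams(D=D, delay=delay)) == \
                pytest.approx(brute_force_pe(list(x), D, delay), abs=1e-12)

    def test_iid_noise_approaches_uniform_limit(self, rng):
        x = rng.standard_normal(20000)
        pe = g.permutation_entropy(x, PeParams(D=3, delay=1))
        assert abs(pe - math.log2(6)) < 0.05

    @given(finite_series)
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounds_and_monotone_invariance(self, x):
        params = PeParams(D=3, delay=1)
        pe = g.permutation_entropy(x, params)
        assert 0.0 <= pe <= math.log2(6) + 1e-12
        transformed = np.exp(x / 50)  # strictly increasing transform
        assert g.permutation_entropy(transformed, params) == \
            pytest.approx(pe, abs=1e-12)

    def test_too_short_series_states_minimum(self):
        with pytest.raises(FeatureError, match="minimum"):
            g.permutation_entropy([1.0, 2.0], PeParams(D=4, delay=2))


class TestZeroCrossingRate:
    def test_alternating_series(self):
        assert g.zero_crossing_rate([1, -1, 1, -1]) == 1.0

    def test_all_positive_series(self):
        assert g.zero_crossing_rate([3.0, 1.0, 2.0]) == 0.0

    def test_exact_zero_belongs_to_preceding_sign(self):
        # 1, 0, 1 never changes sign; 1, 0, -1 crosses once
        assert g.zero_crossing_rate([1.0, 0.0, 1.0]) == 0.0
        assert g.zero_crossing_rate([1.0, 0.0, -1.0]) == pytest.approx(0.5)

    def test_sampled_sine_crossing_count(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 1.0 * t)  # 10 full cycles
        assert g.zero_crossing_rate(x) == pytest.approx(19 / 999)


def _recording(rng, n=400):
    return Recording(
        axes={a: rng.standard_normal(n) for a in AXES}, sampling_rate=50.0)


class TestExtractFeatures:
    def test_exactly_27_canonical_features(self, rng):
        fv = g.extract_features(_recording(rng))
        assert tuple(fv.values) == FEATURE_NAMES
        assert len(fv.values) == 27

    def test_constant_zero_recording(self):
        rec = Recording(axes={a: np.zeros(400) for a in AXES},
                        sampling_rate=50.0)
        fv = g.extract_features(rec, tolerate_undefined=True)
        for axis in AXES:
            for kind in ("MEAN", "MAX", "MIN", "ZCR"):
                assert fv.values[f"{kind} ({axis})"] == 0.0
            for kind in ("MSEM", "CI"):
                assert math.isnan(fv.values[f"{kind} ({axis})"])
        with pytest.raises(FeatureError):
            g.extract_features(rec)

    def test_axis_permutation_permutes_named_values(self, rng):
        data = {a: rng.standard_normal(400) for a in AXES}
        rec = Recording(axes=data, sampling_rate=50.0)
        permuted = Recording(
            axes={"ML": data["V"], "V": data["AP"], "AP": data["ML"]},
            sampling_rate=50.0)
        fv, fv_p = g.extract_features(rec), g.extract_features(permuted)
        for kind in ("MEAN", "STD", "ZCR", "PE", "CI"):
            assert fv.values[f"{kind} (V)"] == fv_p.values[f"{kind} (ML)"]

    def test_min_mean_max_ordering(self, rng):
        fv = g.extract_features(_recording(rng))
        for axis in AXES:
            assert (fv.values[f"MIN ({axis})"]
                    <= fv.values[f"MEAN ({axis})"]
                    <= fv.values[f"MAX ({axis})"])

    def test_positive_scaling_invariances(self, rng):
        data = {a: rng.standard_normal(400) for a in AXES}
        rec = Recording(axes=data, sampling_rate=50.0)
        scaled = Recording(axes={a: 3.5 * v for a, v in data.items()},
                           sampling_rate=50.0)
        fv, fv_s = g.extract_features(rec), g.extract_features(scaled)
        for axis in AXES:
            for kind in ("ZCR", "PE", "MSEM", "MSTD", "CI"):
                assert fv_s.values[f"{kind} ({axis})"] == pytest.approx(
                    fv.values[f"{kind} ({axis})"], abs=1e-9)
            for kind in ("MEAN", "STD", "MAX", "MIN"):
                assert fv_s.values[f"{kind} ({axis})"] == pytest.approx(
                    3.5 * fv.values[f"{kind} ({axis})"])
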