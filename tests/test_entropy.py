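"""Unit and property tests for coarse-graining and multi-scale sample entropy."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_sample_entropy
from gaitmse import EntropyParams, MSEProfile, coarse_grain, mse, mse_report, sample_entropy
from gaitmse.errors import InvalidScaleError, SeriesLengthError, ToleranceError


class TestCoarseGrain:
    @pytest.mark.parametrize(
        "x, s, expected",
        [
            ([1, 3, 5, 7], 2, [2.0, 6.0]),
            ([1, 2, 3, 4, 5, 6, 7], 3, [2.0, 5.0]),  # remainder dropped
            ([4.0, 4.0, 4.0], 3, [4.0]),
        ],
    )
    def test_window_means(self, x, s, expected):
        np.testing.assert_allclose(coarse_grain(x, s), expected)

    def test_scale_one_is_identity(self):
        x = np.random.default_rng(0).normal(size=50)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_output_length_is_floor(self):
        rng = np.random.default_rng(1)
        for n in (5, 17, 100):
            x = rng.normal(size=n)
            for s in range(1, n + 1):
                assert coarse_grain(x, s).size == n // s

    def test_scale_out_of_range(self):
        with pytest.raises(InvalidScaleError):
            coarse_grain([1.0, 2.0], 3)
        with pytest.raises(InvalidScaleError):
            coarse_grain([1.0, 2.0], 0)


class TestSampleEntropy:
    def test_constant_series_zero_entropy(self):
        # every template matches every other at both lengths: -ln(1) = 0
        assert sample_entropy(np.full(30, 7.0), m=2, r=0.1) == 0.0

    def test_matches_oracle_alternating(self):
        x = np.array([1.0, 2.0] * 10)
        r = 0.2 * np.std(x, ddof=1)
        assert abs(sample_entropy(x, 2, r) - brute_force_sample_entropy(x, 2, r)) < 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_gaussian(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=120)
        r = 0.25 * np.std(x, ddof=1)
        ours = sample_entropy(x, 2, r)
        theirs = brute_force_sample_entropy(x, 2, r)
        assert abs(ours - theirs) < 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.floats(-10, 10), min_size=10, max_size=60),
        m=st.integers(1, 2),
        r=st.floats(0.05, 1.0),
    )
    def test_oracle_equivalence_property(self, data, m, r):
        x = np.asarray(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ours = sample_entropy(x, m, r)
        theirs = brute_force_sample_entropy(x, m, r)
        if np.isnan(theirs):
            assert np.isnan(ours)
        else:
            assert abs(ours - theirs) < 1e-12

    def test_nonnegative_when_defined(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=100)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = sample_entropy(x, 2, 0.25 * np.std(x, ddof=1))
            assert np.isnan(v) or v >= 0

    def test_affine_invariance_with_sd_scaled_r(self):
        # entropy(a*x + b) == entropy(x) when r scales with the SD
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        r_frac = 0.25
        v1 = sample_entropy(x, 2, r_frac * np.std(x, ddof=1))
        y = 3.7 * x - 11.0
        v2 = sample_entropy(y, 2, r_frac * np.std(y, ddof=1))
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_error_contracts(self):
        with pytest.raises(SeriesLengthError):
            sample_entropy([1.0, 2.0, 3.0], m=2, r=0.1)
        with pytest.raises(ToleranceError):
            sample_entropy(np.ones(20), m=2, r=0.0)

    def test_zero_matches_returns_nan_not_crash(self):
        # strictly increasing with huge steps: no template pairs within r
        x = np.arange(20.0) * 100.0
        with pytest.warns(UserWarning):
            assert np.isnan(sample_entropy(x, 2, 1e-6))


class TestMSE:
    def test_scale_one_equals_sample_entropy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        params = EntropyParams(m=2, r_frac=0.25, max_scale=4)
        prof = mse(x, params)
        direct = sample_entropy(x, 2, 0.25 * np.std(x, ddof=1))
        assert prof.entropy_at(1) == direct
        assert prof.samp_en == direct

    def test_band_means(self):
        prof = MSEProfile(
            entropy_by_scale=np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4]),
            sd_original=1.0,
            params=EntropyParams(max_scale=6),
            n_input=100,
        )
        assert prof.mse_s == pytest.approx(0.8)
        assert prof.mse_l == pytest.approx(0.5)

    def test_white_noise_entropy_decreases_with_scale(self):
        # coarse-graining averages away variance while r stays fixed, so
        # the profile of white noise falls monotonically (in the mean)
        params = EntropyParams()
        profiles = []
        for seed in range(15):
            x = np.random.default_rng(seed).normal(size=1000)
            profiles.append(mse(x, params).entropy_by_scale)
        mean_profile = np.mean(profiles, axis=0)
        assert np.all(np.diff(mean_profile) < 0)

    def test_too_short_series_names_minimum(self):
        with pytest.raises(SeriesLengthError, match="24"):
            mse(np.random.default_rng(0).normal(size=10), EntropyParams(max_scale=6))

    def test_constant_series_tolerance_error(self):
        with pytest.raises(ToleranceError, match="absolute"):
            mse(np.ones(100), EntropyParams())

    def test_shuffle_never_decreases_entropy_of_structured_series(self):
        # periodic-plus-small-noise: random permutation destroys structure
        rng = np.random.default_rng(6)
        t = np.arange(300)
        base = np.sin(2 * np.pi * t / 20) + rng.normal(0, 0.1, 300)
        r = 0.25 * np.std(base, ddof=1)
        original = sample_entropy(base, 2, r)
        increased = 0
        for _ in range(100):
            shuffled = rng.permutation(base)
            if sample_entropy(shuffled, 2, r) >= original:
                increased += 1
        assert increased >= 95


class TestMSEReport:
    def test_single_series_row_matches_profile(self):
        x = np.random.default_rng(7).normal(size=400)
        params = EntropyParams()
        report = mse_report({"walk": [x]}, params)
        prof = mse(x, params)
        row = report.table.iloc[0]
        assert row["sampen_mean"] == prof.samp_en
        assert row["mse_s_mean"] == prof.mse_s
        assert row["mse_l_mean"] == prof.mse_l
        assert row["sampen_sd"] == 0.0

    def test_identical_conditions_zero_pairwise_diff(self):
        x = np.random.default_rng(8).normal(size=400)
        report = mse_report({"a": [x], "b": [x.copy()]})
        assert report.pairwise_mse_s["mse_s_diff"].iloc[0] == 0.0

    def test_accepts_bare_array(self):
        x = np.random.default_rng(9).normal(size=400)
        report = mse_report({"only": x})
        assert report.table.iloc[0]["n_series"] == 1
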