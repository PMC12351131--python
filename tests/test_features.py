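"""Moment features: frozen examples, invariants, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiocycle.features import (
    classical_moments,
    extract_features,
    median_center,
    median_kurtosis,
    median_skewness,
    median_std,
    median_variance,
)
from cardiocycle.segmentation import CycleSet

from oracles import (
    oracle_classical,
    oracle_median,
    oracle_median_kurtosis,
    oracle_median_skewness,
    oracle_median_variance,
)


def relclose(a, b, tol=1e-9):
    return abs(a - b) <= tol * max(1.0, abs(b))


class TestScalarExamples:
    def test_median_odd_even(self):
        assert median_center([1, 2, 3, 4, 5]) == 3
        assert median_center([1, 2, 3, 4]) == 2.5

    def test_median_variance_hand_values(self):
        # eta=3, squared deviations 4,1,0,1,4 -> 10/5
        assert median_variance([1, 2, 3, 4, 5]) == pytest.approx(2.0)
        assert median_variance([7.0, 7.0, 7.0]) == 0.0
        # outlier case: median-centered exceeds mean-centered dispersion
        assert median_variance([1, 2, 3, 4, 10]) == pytest.approx(11.0)
        assert classical_moments([1, 2, 3, 4, 10])[1] == pytest.approx(10.0)

    def test_median_std(self):
        assert median_std([1, 2, 3, 4, 5]) == pytest.approx(np.sqrt(2.0))
        assert median_std([4.2, 4.2]) == 0.0

    def test_median_skewness_symmetric_and_outlier(self):
        assert median_skewness([1, 2, 3, 4, 5]) == pytest.approx(0.0, abs=1e-12)
        # sum of cubes 335, /5 = 67, sigma_eta^3 = 11^1.5
        expect = 67.0 / 11.0 ** 1.5
        assert median_skewness([1, 2, 3, 4, 10]) == pytest.approx(expect)
        # as-printed convention omits the 1/N
        assert median_skewness([1, 2, 3, 4, 10], raw=True) == pytest.approx(5 * expect)

    def test_median_kurtosis_extremes(self):
        # symmetric two-point mass attains the minimum
        assert median_kurtosis([-1.0, 1.0]) == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100_000)
        assert median_kurtosis(x) == pytest.approx(3.0, abs=0.1)

    def test_classical_moments_hand_values(self):
        m, v, s, k = classical_moments([1, 2, 3, 4, 5])
        assert (m, v, s) == pytest.approx((3.0, 2.0, 0.0))
        assert k == pytest.approx(1.7)  # sum d^4 = 34; 34/5/4

    def test_zero_dispersion_raises(self):
        for fn in (median_skewness, median_kurtosis):
            with pytest.raises(ValueError):
                fn([3.0, 3.0, 3.0])
        with pytest.raises(ValueError):
            classical_moments([3.0, 3.0])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            median_center([])


class TestInvariants:
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=64))
    @settings(derandomize=True, max_examples=100)
    def test_median_variance_dominates_mean_variance(self, xs):
        # the mean minimizes the sum of squared deviations
        eta_var = oracle_median_variance(xs)
        mean_var = sum((x - sum(xs) / len(xs)) ** 2 for x in xs) / len(xs)
        assert median_variance(xs) >= mean_var - 1e-9
        assert median_variance(xs) == pytest.approx(eta_var, rel=1e-9, abs=1e-12)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=32))
    @settings(derandomize=True, max_examples=100)
    def test_median_permutation_invariance(self, xs):
        shuffled = list(reversed(sorted(xs)))
        assert median_center(xs) == median_center(shuffled)

    def test_scale_equivariance_and_sign_flip(self, rng):
        x = rng.normal(size=50)
        for a in (-3.0, 0.5, 7.0):
            assert median_std(a * x) == pytest.approx(abs(a) * median_std(x))
            assert median_skewness(-x) == pytest.approx(-median_skewness(x))

    def test_affine_invariance_of_standardized_moments(self, rng):
        x = rng.normal(size=80)
        for a, b in ((2.5, 1.0), (-1.5, -4.0)):
            assert median_kurtosis(a * x + b) == pytest.approx(median_kurtosis(x), rel=1e-9)
            _, _, s0, k0 = classical_moments(x)
            _, _, s1, k1 = classical_moments(a * x + b)
            assert k1 == pytest.approx(k0, rel=1e-9)
            assert s1 == pytest.approx(np.sign(a) * s0, rel=1e-9)

    def test_median_bounded_under_single_outlier(self, rng):
        # replacing one element with M moves the median by a bounded amount
        # independent of M, while the mean diverges linearly in M
        x = rng.normal(size=11)
        base = median_center(x)
        deltas = []
        for M in (1e3, 1e6, 1e12):
            y = x.copy()
            y[0] = M
            deltas.append(abs(median_center(y) - base))
            assert abs(np.mean(y) - np.mean(x)) > M / 20
        assert max(deltas) == deltas[0] == deltas[-1]  # saturates, M-independent
        assert max(deltas) <= np.ptp(x)

    def test_symmetric_data_mean_equals_median_features(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        m, v, s, k = classical_moments(x)
        assert median_variance(x) == pytest.approx(v)
        assert median_skewness(x) == pytest.approx(s)
        assert median_kurtosis(x) == pytest.approx(k)


class TestOracleAgreement:
    def test_random_vectors_against_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 65))
            xs = list(rng.normal(scale=rng.uniform(0.1, 10), size=n))
            assert relclose(median_center(xs), oracle_median(xs))
            assert relclose(median_variance(xs), oracle_median_variance(xs))
            assert relclose(median_skewness(xs), oracle_median_skewness(xs))
            assert relclose(median_kurtosis(xs), oracle_median_kurtosis(xs))
            got = classical_moments(xs)
            want = oracle_classical(xs)
            for g, w in zip(got, want):
                assert relclose(g, w)


def _cycle_set(rows):
    rows = np.asarray(rows, dtype=float)
    return CycleSet(
        cycles=rows,
        L=rows.shape[1],
        r_offset=rows.shape[1] // 3,
        subject_id="S1",
        label="healthy",
        source_peaks=np.arange(rows.shape[0]) * rows.shape[1],
    )


class TestExtractFeatures:
    def test_rows_match_scalar_ops(self, rng):
        rows = rng.normal(size=(100, 48))
        cs = _cycle_set(rows)
        for kind, var_fn, skew_fn, kurt_fn in (
            ("median", oracle_median_variance, oracle_median_skewness, oracle_median_kurtosis),
        ):
            feats = extract_features(cs, center_kind=kind)
            for i in range(rows.shape[0]):
                xs = list(rows[i])
                assert relclose(feats.variance[i], var_fn(xs))
                assert relclose(feats.skewness[i], skew_fn(xs))
                assert relclose(feats.kurtosis[i], kurt_fn(xs))

    def test_identical_symmetric_rows(self):
        row = np.array([-2.0, -1.0, 0.0, 1.0, 2.0, 0.0])
        cs = _cycle_set(np.tile(row, (5, 1)))
        fm = extract_features(cs, "median")
        fa = extract_features(cs, "mean")
        assert fm.n_cycles == 5
        assert np.allclose(fm.skewness, 0.0)
        for attr in ("center", "variance", "skewness", "kurtosis"):
            assert np.allclose(getattr(fm, attr), getattr(fa, attr))

    def test_zero_dispersion_rows_excluded_not_fatal(self, rng):
        rows = rng.normal(size=(4, 16))
        rows[2] = 5.0  # constant row: undefined standardized moments
        feats = extract_features(_cycle_set(rows), "median")
        assert feats.n_cycles == 3
        assert feats.n_excluded == 1

    def test_label_and_subject_propagated(self, rng):
        feats = extract_features(_cycle_set(rng.normal(size=(3, 8))), "mean")
        df = feats.to_dataframe()
        assert set(df["subject_id"]) == {"S1"}
        assert set(df["label"]) == {"healthy"}
        assert set(df["center_kind"]) == {"mean"}
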