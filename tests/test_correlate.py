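import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from elina.correlate import (
    CorrelateError,
    FractionPackage,
    cov_corr_kernel,
    enumerate_packages,
    hetca,
    hot_cold_report,
    stocsy,
)
from elina.preprocess import BucketTable
from elina.spectra_io import FractionSeries
from elina.synthetic import ElutionProfile, SyntheticCompound, simulate_campaign
from elina import preprocess

from _oracles import brute_cov_corr


def _table(values):
    values = np.asarray(values, dtype=float)
    n_f, n_b = values.shape
    return BucketTable(
        left_edges=np.arange(n_b) * 0.1,
        width=0.1,
        values=values,
        fraction_ids=tuple(f"F{i}" for i in range(n_f)),
    )


PKG3 = FractionPackage((0, 1, 2))


class TestFractionPackage:
    def test_non_consecutive_rejected(self):
        with pytest.raises(CorrelateError, match="consecutive"):
            FractionPackage((0, 2, 3))

    def test_singleton_rejected(self):
        with pytest.raises(CorrelateError, match=">=2"):
            FractionPackage((5,))

    def test_enumerate_counts_windows(self):
        series = FractionSeries(
            fraction_ids=tuple(f"F{i}" for i in range(32)),
            shared_ppm=np.linspace(0, 1, 4),
            spectra_matrix=np.zeros((32, 4)),
            activity=np.arange(32.0),
        )
        pkgs = enumerate_packages(series, size=3)
        assert len(pkgs) == 30  # n - size + 1
        assert pkgs[0].member_indices == (0, 1, 2)
        # sample variance of (0, 1, 2) is 1
        assert pkgs[0].activity_variance == pytest.approx(1.0)

    def test_single_full_window_and_undersized_error(self):
        series = FractionSeries(
            fraction_ids=("a", "b", "c"),
            shared_ppm=np.linspace(0, 1, 4),
            spectra_matrix=np.zeros((3, 4)),
            activity=np.arange(3.0),
        )
        pkgs = enumerate_packages(series, size=3)
        assert len(pkgs) == 1 and pkgs[0].member_indices == (0, 1, 2)
        series2 = FractionSeries(
            fraction_ids=("a", "b"),
            shared_ppm=np.linspace(0, 1, 4),
            spectra_matrix=np.zeros((2, 4)),
            activity=np.arange(2.0),
        )
        with pytest.raises(CorrelateError):
            enumerate_packages(series2, size=3)
        with pytest.raises(CorrelateError):
            enumerate_packages(series, size=1)


class TestHetca:
    def test_constant_activity_all_neutral_with_warning(self):
        table = _table(np.arange(12.0).reshape(3, 4))
        with pytest.warns(UserWarning, match="constant"):
            res = hetca(table, np.full(3, 42.0), PKG3)
        assert np.all(res.covariance == 0.0)
        assert np.all(np.isnan(res.correlation))
        assert np.all(res.labels == "neutral")

    def test_bucket_tracking_activity_is_hot(self):
        act = np.array([1.0, 5.0, 3.0])
        values = np.zeros((3, 3))
        values[:, 1] = act
        res = hetca(_table(values), act, PKG3, threshold=1.0)
        assert res.correlation[1] == pytest.approx(1.0)
        assert res.labels[1] == "hot"
        # empty buckets are undefined, never "uncorrelated evidence"
        assert np.isnan(res.correlation[0])
        assert res.labels[0] == "neutral"

    def test_small_integer_example_matches_brute_force(self):
        values = np.array(
            [[1, 2, 3, 4, 0],
             [2, 4, 1, 4, 0],
             [5, 8, 2, 4, 0]], dtype=float
        )
        act = np.array([10.0, 20.0, 40.0])
        res = hetca(_table(values), act, PKG3)
        cov_o, corr_o = brute_cov_corr(values.tolist(), act.tolist())
        np.testing.assert_allclose(res.covariance, cov_o, rtol=1e-12)
        np.testing.assert_allclose(res.correlation, corr_o, rtol=1e-12)

    def test_labels_follow_threshold_rule(self, rng):
        values = rng.normal(size=(3, 50))
        act = rng.normal(size=3)
        res = hetca(_table(values), act, PKG3, threshold=0.6)
        defined = ~np.isnan(res.correlation)
        assert np.all(
            (res.labels[defined] == "hot")
            == (res.correlation[defined] >= 0.6)
        )
        assert np.all(
            (res.labels[defined] == "cold")
            == (res.correlation[defined] <= -0.6)
        )


class TestStocsy:
    def test_driver_self_correlation_is_exactly_one(self, rng):
        values = rng.normal(size=(3, 6))
        res = stocsy(_table(values), driver_ppm=0.25, package=PKG3)
        assert res.driver_bucket == 2  # nearest centre to 0.25 among k*0.1+0.05
        assert res.correlation[res.driver_bucket] == 1.0

    def test_affine_colinear_bucket(self):
        driver = np.array([1.0, 3.0, 2.0])
        values = np.column_stack([driver, 2.0 * driver + 5.0])
        res = stocsy(_table(values), driver_ppm=0.05, package=PKG3)
        assert res.correlation[1] == pytest.approx(1.0)
        assert res.covariance[1] == pytest.approx(2.0 * np.var(driver, ddof=1))

    def test_driver_outside_range_and_zero_variance(self):
        table = _table(np.ones((3, 4)))
        with pytest.raises(CorrelateError, match="outside"):
            stocsy(table, driver_ppm=9.9, package=PKG3)
        with pytest.raises(CorrelateError, match="zero variance"):
            stocsy(table, driver_ppm=0.05, package=PKG3)

    def test_stocsy_equals_hetca_with_driver_as_response(self, rng):
        # the two analyses share one kernel: STOCSY with driver d must equal
        # HetCA run with activity := the driver bucket's intensities
        values = rng.normal(size=(3, 20))
        table = _table(values)
        res_s = stocsy(table, driver_ppm=0.55, package=PKG3)
        d = res_s.driver_bucket
        res_h = hetca(table, _pad_activity(values[:, d], 3), PKG3)
        np.testing.assert_allclose(res_s.covariance, res_h.covariance, rtol=1e-12)
        others = np.arange(20) != d
        np.testing.assert_allclose(
            res_s.correlation[others], res_h.correlation[others], rtol=1e-12
        )

    def test_two_compound_mixture_separates_molecules(self):
        # compound P (resonances 5.12, 1.60, 1.65) and compound Q (4.05,
        # 0.90) with independent elution profiles; STOCSY at 5.12 over a
        # window seeing both must tie P's resonances together (> 0.99) and
        # leave Q's nearly uncorrelated (|r| < 0.5)
        p = SyntheticCompound(
            "P", ((5.12, 0.004, 1.0), (1.60, 0.004, 3.0), (1.65, 0.004, 3.0))
        )
        q = SyntheticCompound("Q", ((4.05, 0.004, 1.0), (0.90, 0.004, 3.0)))
        series, _, _ = simulate_campaign(
            [p, q],
            [
                ElutionProfile(peak_fraction=6.0, spread=1.2, amplitude=1.0),
                ElutionProfile(peak_fraction=17.0, spread=1.2, amplitude=1.0),
            ],
            n_fractions=24,
            grid=(0.5, 7.0, 26001),
            noise={"spectral_sd": 0.02, "activity_sd": 0.0,
                   "baseline_coefficients": (0, 0, 0, 0, 0)},
            seed=11,
        )
        table = preprocess.bucket(series, 0.5, 7.0, 0.0005)
        pkg = FractionPackage(tuple(range(24)))
        res = stocsy(table, 5.12, pkg)

        def at(ppm):
            return res.correlation[int(np.argmin(np.abs(table.centres - ppm)))]

        assert at(1.60) > 0.99 and at(1.65) > 0.99
        assert abs(at(4.05)) < 0.5 and abs(at(0.90)) < 0.5
        # and the whole vector agrees with the brute-force oracle
        d = res.driver_bucket
        sub = table.values[list(pkg.member_indices)]
        cov_o, corr_o = brute_cov_corr(sub.tolist(), sub[:, d].tolist())
        np.testing.assert_allclose(res.covariance, cov_o, rtol=1e-10)


def _pad_activity(window_values, n):
    """Activity vector over the full table whose package rows equal the
    given values (package is the first n rows here)."""
    return np.asarray(window_values, dtype=float)


class TestKernelProperties:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(3, 8))
        y = rng.normal(size=3)
        cov, corr = cov_corr_kernel(X, y)
        cov_o, corr_o = brute_cov_corr(X.tolist(), y.tolist())
        np.testing.assert_allclose(cov, cov_o, rtol=1e-12)
        np.testing.assert_allclose(corr, corr_o, rtol=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 100.0),
        st.floats(-50.0, 50.0),
    )
    def test_scale_and_shift_behaviour(self, seed, c, shift):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(4, 6))
        y = rng.normal(size=4)
        cov0, corr0 = cov_corr_kernel(X, y)
        # positive scaling of one bucket scales its covariance, not its corr
        X2 = X.copy()
        X2[:, 2] *= c
        cov2, corr2 = cov_corr_kernel(X2, y)
        assert cov2[2] == pytest.approx(c * cov0[2], rel=1e-9)
        assert corr2[2] == pytest.approx(corr0[2], rel=1e-9)
        # constant shifts of a bucket or of the response change nothing
        X3 = X.copy()
        X3[:, 1] += shift
        cov3, corr3 = cov_corr_kernel(X3, y + shift)
        np.testing.assert_allclose(cov3, cov0, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(corr3, corr0, rtol=1e-9, atol=1e-12)


class TestHotColdReport:
    def test_all_neutral_gives_empty_report(self):
        res = hetca(_table(np.ones((3, 5))), np.array([1.0, 2.0, 3.0]), PKG3)
        assert hot_cold_report(res) == []

    def test_single_hot_run_reported_as_one_interval(self):
        act = np.array([1.0, 2.0, 3.0])
        values = np.zeros((3, 8))
        for j in (2, 3, 4, 5):
            values[:, j] = act * (j + 1)
        res = hetca(_table(values), act, PKG3)
        report = hot_cold_report(res, min_run=2)
        assert len(report) == 1
        iv = report[0]
        assert iv.label == "hot" and iv.n_buckets == 4
        assert iv.ppm_low == pytest.approx(0.2)
        assert iv.ppm_high == pytest.approx(0.6)

    def test_short_runs_suppressed_and_sorting_by_covariance(self):
        act = np.array([1.0, 2.0, 3.0])
        values = np.zeros((3, 10))
        values[:, 1] = act          # isolated hot bucket: below min_run
        values[:, 4] = act * 10
        values[:, 5] = act * 10
        values[:, 7] = -act * 100
        values[:, 8] = -act * 100
        res = hetca(_table(values), act, PKG3)
        report = hot_cold_report(res, min_run=2)
        assert [iv.label for iv in report] == ["cold", "hot"]
        assert abs(report[0].peak_covariance) > abs(report[1].peak_covariance)
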