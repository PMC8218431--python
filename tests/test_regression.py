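"""Core LD score regression: exact algebra, jackknife, Wald test, liability
transform, and sklearn estimator conventions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from gxesum import (
    GxESum,
    fit_gxesum,
    jackknife_se,
    observed_to_liability,
    rxe_from_intercept,
    wald_test,
)
from gxesum.regression import GxEEstimate, _block_jackknife, _wls


def _make_sumstats(l2, chisq, n=10000):
    snp = [f"s{i}" for i in range(len(l2))]
    ss = pd.DataFrame({"SNP": snp, "N": n, "CHISQ": chisq})
    ld = pd.DataFrame({"SNP": snp, "L2": l2})
    return ss, ld


class TestExactAlgebra:
    def test_flat_unit_chisq_is_exact_null(self):
        rng = np.random.default_rng(41)
        l2 = rng.uniform(1, 10, 1000)
        ss, ld = _make_sumstats(l2, np.ones(1000))
        est = fit_gxesum(ss, ld, kurtosis=3.0)
        assert abs(est.h2_g1) < 1e-12
        assert abs(est.intercept - 1.0) < 1e-12
        assert abs(est.h2_tau1) < 1e-12
        assert est.p_wald == 1.0

    @pytest.mark.parametrize("weighting", ["ldsc", "none"])
    def test_noise_free_line_recovered(self, weighting):
        n, m = 10000, 2000
        rng = np.random.default_rng(42)
        l2 = rng.uniform(1, 20, m)
        chisq = n * 0.05 / m * l2 + 1.1  # 1.1 = 1 + 2*0.05 + 2*0, so tau1 = 0
        ss, ld = _make_sumstats(l2, chisq, n=n)
        est = fit_gxesum(ss, ld, kurtosis=3.0, weighting=weighting)
        assert abs(est.h2_g1 - 0.05) < 1e-10
        assert abs(est.h2_tau1) < 1e-10
        assert est.se_h2_g1 < 1e-10

    def test_nonzero_rxe_line(self):
        n, m = 20000, 1000
        l2 = np.linspace(1, 15, m)
        chisq = n * 0.02 / m * l2 + (1 + 2 * 0.02 + 2 * 0.1)
        ss, ld = _make_sumstats(l2, chisq, n=n)
        est = fit_gxesum(ss, ld, kurtosis=3.0)
        assert abs(est.h2_g1 - 0.02) < 1e-10
        assert abs(est.h2_tau1 - 0.1) < 1e-10

    def test_kurtosis_three_reduces_to_normal_case(self):
        import warnings as _w

        for intercept, h2 in [(1.3, 0.05), (1.0, 0.0), (0.97, 0.02)]:
            with _w.catch_warnings():
                _w.simplefilter("ignore")  # the 0.97 case is legitimately negative
                general = rxe_from_intercept(intercept, h2, kurtosis=3.0)
            special = (intercept - 1.0 - 2.0 * h2) / 2.0
            assert general == special  # bit-for-bit

    def test_intercept_round_trip(self):
        """Rebuilding E[chisq] from the decomposition reproduces the line."""
        n, m = 15000, 500
        rng = np.random.default_rng(43)
        l2 = rng.uniform(1, 12, m)
        chisq = n * 0.03 / m * l2 + 1.35
        ss, ld = _make_sumstats(l2, chisq, n=n)
        for kurt in (3.0, 4.5):
            est = fit_gxesum(ss, ld, kurtosis=kurt)
            rebuilt = (
                n * est.h2_g1 / m * l2
                + 1.0
                + (kurt - 1.0) * (est.h2_g1 + est.h2_tau1)
            )
            np.testing.assert_allclose(rebuilt, chisq, atol=1e-9)

    def test_rxe_from_intercept_values(self):
        assert rxe_from_intercept(1.0, 0.0, 3.0) == 0.0
        assert abs(rxe_from_intercept(1.3, 0.05, 3.0) - 0.10) < 1e-12
        assert abs(rxe_from_intercept(1.2, 0.02, 9.0) - 0.005) < 1e-12
        with pytest.raises(ValueError):
            rxe_from_intercept(1.2, 0.1, kurtosis=1.0)
        with pytest.warns(UserWarning, match="negative"):
            rxe_from_intercept(0.8, 0.0, 3.0)


class TestWald:
    def test_closed_forms(self):
        assert wald_test(0.0, 1.0) == 1.0
        assert abs(wald_test(1.959964, 1.0) - 0.05) < 1e-6
        assert abs(wald_test(3.0, 1.0) - 0.0026998) < 1e-6
        assert abs(wald_test(-3.0, 1.0) - 0.0026998) < 1e-6  # two-sided

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            wald_test(0.1, 0.0)


class TestJackknife:
    def test_homogeneous_blocks_give_zero_se(self):
        # identical (x, chisq) pattern in every block: no between-block variance
        block_l2 = np.linspace(1, 5, 10)
        block_chisq = 0.3 * block_l2 + 1.0
        l2 = np.tile(block_l2, 40)
        chisq = np.tile(block_chisq, 40)
        ss, ld = _make_sumstats(l2, chisq)
        se_h2, se_int = jackknife_se(ss, ld, n_blocks=40, weighting="none")
        assert se_h2 < 1e-10
        assert se_int < 1e-10

    def test_two_block_hand_enumeration(self):
        """B=2 on 4 SNPs: both leave-one-out OLS fits written out by hand."""
        l2 = np.array([1.0, 2.0, 3.0, 5.0])
        chisq = np.array([1.1, 1.4, 1.2, 1.9])
        n = 1000.0

        def ols(x, y):
            slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
            return slope, y.mean() - slope * x.mean()

        x = n / 4 * l2
        fits = [ols(x[2:], chisq[2:]), ols(x[:2], chisq[:2])]  # delete blocks 1, 2
        slopes = np.array([f[0] for f in fits])
        ints = np.array([f[1] for f in fits])
        se_slope = np.sqrt(1.0 / 2.0 * ((slopes - slopes.mean()) ** 2).sum())
        se_int = np.sqrt(1.0 / 2.0 * ((ints - ints.mean()) ** 2).sum())

        ss, ld = _make_sumstats(l2, chisq, n=n)
        got_slope, got_int = jackknife_se(ss, ld, n_blocks=2, weighting="none")
        assert abs(got_slope - se_slope) < 1e-10
        assert abs(got_int - se_int) < 1e-10

    def test_jackknife_tracks_replicate_sd(self):
        """On repeated noisy draws around a fixed line, the block jackknife SE
        should approximate the between-replicate SD of the slope."""
        rng = np.random.default_rng(44)
        m, n = 3000, 5000
        l2 = rng.uniform(1, 10, m)
        mu = n * 0.01 / m * l2 + 1.1
        h2s, ses = [], []
        for _ in range(60):
            chisq = mu * rng.chisquare(1, m)  # chi-square noise around the line
            ss, ld = _make_sumstats(l2, chisq, n=n)
            est = fit_gxesum(ss, ld)
            h2s.append(est.h2_g1)
            ses.append(est.se_h2_g1)
        emp_sd = np.std(h2s, ddof=1)
        assert abs(np.mean(ses) / emp_sd - 1) < 0.3

    def test_invalid_block_count(self):
        with pytest.raises(ValueError):
            _block_jackknife(np.arange(10.0), np.arange(10.0), np.ones(10), 11)


class TestLiabilityTransform:
    def test_zero_is_fixed_point(self):
        est = GxEEstimate(0.0, 0.1, 1.0, 0.1, 0.0, 3.0, 1.0, 1000, 500)
        for k in (0.025, 0.1, 0.5):
            assert observed_to_liability(est, k).h2_g1 == 0.0

    def test_half_prevalence_factor_is_pi_over_two(self):
        est = GxEEstimate(0.10, 0.02, 1.0, 0.1, 0.0, 3.0, 0.5, 1000, 500)
        out = observed_to_liability(est, 0.5)
        assert abs(out.h2_g1 - 0.15708) < 1e-5
        assert abs(out.h2_g1 / est.h2_g1 - np.pi / 2) < 1e-12
        assert abs(out.se_h2_g1 / est.se_h2_g1 - np.pi / 2) < 1e-12
        assert out.scale == "liability"
        assert out.prevalence == 0.5

    def test_prevalence_point_one(self):
        est = GxEEstimate(0.05, 0.01, 1.0, 0.1, 0.0, 3.0, 0.5, 1000, 500)
        out = observed_to_liability(est, 0.1)
        t = stats.norm.ppf(0.9)
        expected = 0.05 * 0.1 * 0.9 / stats.norm.pdf(t) ** 2
        assert abs(out.h2_g1 - expected) < 1e-12
        assert abs(out.h2_g1 - 0.14612) < 5e-5  # quoted value uses a rounded threshold

    def test_factor_monotone_as_prevalence_vanishes(self):
        est = GxEEstimate(0.05, 0.01, 1.0, 0.1, 0.0, 3.0, 0.5, 1000, 500)
        ks = [0.5, 0.2, 0.1, 0.05, 0.025, 0.01]
        factors = [observed_to_liability(est, k).h2_g1 / 0.05 for k in ks]
        assert all(np.diff(factors) > 0)
        assert min(factors) >= np.pi / 2 - 1e-12

    def test_errors(self):
        est = GxEEstimate(0.05, 0.01, 1.0, 0.1, 0.0, 3.0, 0.5, 1000, 500)
        with pytest.raises(ValueError):
            observed_to_liability(est, 0.0)
        liab = observed_to_liability(est, 0.1)
        with pytest.raises(ValueError, match="observed"):
            observed_to_liability(liab, 0.1)


class TestEstimatorInterface:
    def test_sklearn_conventions(self):
        model = GxESum(kurtosis=4.0, n_blocks=20)
        params = model.get_params()
        assert params["kurtosis"] == 4.0
        cloned = clone(model)
        assert cloned.get_params() == params
        rng = np.random.default_rng(45)
        l2 = rng.uniform(1, 10, 500)
        chisq = 1.0 + 0.1 * l2 + rng.normal(0, 0.05, 500)
        model.fit(l2, chisq, sample_size=5000)
        for attr in ("h2_g1_", "intercept_", "h2_tau1_", "se_h2_g1_", "p_value_"):
            assert hasattr(model, attr)
        pred = model.predict(l2)
        np.testing.assert_allclose(
            pred, model.intercept_ + model.h2_g1_ * 5000 / 500 * l2, atol=1e-12
        )

    def test_requires_sample_size_and_enough_snps(self):
        model = GxESum()
        with pytest.raises(ValueError, match="sample_size"):
            model.fit(np.ones(300), np.ones(300))
        with pytest.raises(ValueError, match="SNPs"):
            model.fit(np.arange(50.0), np.ones(50), sample_size=100)

    def test_kurtosis_bound(self):
        with pytest.raises(ValueError, match="kurtosis"):
            GxESum(kurtosis=1.0).fit(
                np.arange(300.0), np.ones(300), sample_size=100
            )

    def test_max_chisq_filter(self):
        rng = np.random.default_rng(46)
        l2 = rng.uniform(1, 10, 400)
        chisq = rng.chisquare(1, 400)
        chisq[5] = 500.0
        est_all = GxESum().fit(l2, chisq, sample_size=1000)
        est_clip = GxESum(max_chisq=80).fit(l2, chisq, sample_size=1000)
        assert est_clip.m_ == 399
        assert est_all.m_ == 400

    def test_wls_matches_numpy_polyfit(self):
        rng = np.random.default_rng(47)
        x = rng.uniform(0, 5, 100)
        y = 2 * x + 1 + rng.normal(0, 0.1, 100)
        w = rng.uniform(0.5, 2, 100)
        slope, intercept = _wls(x, y, w)
        ref = np.polyfit(x, y, 1, w=np.sqrt(w))
        assert abs(slope - ref[0]) < 1e-10
        assert abs(intercept - ref[1]) < 1e-10
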