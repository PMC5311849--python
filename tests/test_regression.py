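"""Weighted reverse regression: enumeration, fitting, LRT, BIC."""

import math

import numpy as np
import pytest
from scipy import stats

from multiburden.burden import BurdenVector
from multiburden.errors import (
    DegenerateVarianceError,
    RegionSkipped,
    SingularModelError,
    UsageError,
)
from multiburden.formats import PhenotypeTable
from multiburden.regression import (
    analyse_region,
    best_bic_fit,
    bic,
    bonferroni_threshold,
    complete_cases,
    enumerate_models,
    fit_null,
    fit_weighted_lm,
    lrt_pvalue,
)


def wls_oracle(z, y, w):
    """Loop-coded weighted normal-equations solver, independent of the
    implementation under test."""
    z, w = np.asarray(z, float), np.asarray(w, float)
    y = np.atleast_2d(np.asarray(y, float).T).T
    n = len(z)
    x = np.column_stack([np.ones(n), y])
    p = x.shape[1]
    a = np.zeros((p, p))
    b = np.zeros(p)
    for i in range(n):
        for r in range(p):
            b[r] += w[i] * x[i, r] * z[i]
            for c in range(p):
                a[r, c] += w[i] * x[i, r] * x[i, c]
    coef = np.linalg.solve(a, b)
    wrss = sum(w[i] * (z[i] - x[i] @ coef) ** 2 for i in range(n))
    sigma2 = wrss / n
    loglik = 0.5 * sum(math.log(wi) for wi in w) - 0.5 * n * (
        math.log(2 * math.pi * sigma2) + 1
    )
    ses = np.sqrt(np.diag(np.linalg.inv(a)) * wrss / (n - p))
    return coef, ses, loglik


def _table(y):
    """PhenotypeTable around an (N, K) matrix with columns p1..pK."""
    y = np.atleast_2d(np.asarray(y, float).T).T
    n, k = y.shape
    names = ["ID_1"] + [f"p{j + 1}" for j in range(k)]
    values = np.column_stack([np.full(n, np.nan), y])
    return PhenotypeTable(
        [f"i{i}" for i in range(n)], names, ["0"] + ["P"] * k, values
    )


def _burden(z, n_counts):
    z = np.asarray(z, float)
    n = np.asarray(n_counts)
    return BurdenVector(
        r=z * 2 * n, n=n, z=np.where(n > 0, z, np.nan), w=n.astype(float),
        excluded=n == 0, variants=[("rs1", 0.01)],
    )


class TestEnumerateModels:
    def test_two_phenotypes_three_models_full_first(self):
        labels = [m.label for m in enumerate_models(["a", "b"])]
        assert labels == ["a+b", "a", "b"]

    @pytest.mark.parametrize("k, count", [(1, 1), (2, 3), (4, 15), (8, 255), (10, 1023)])
    def test_model_count_identity(self, k, count):
        assert len(enumerate_models([f"p{i}" for i in range(k)])) == count

    def test_ordering_by_size_then_index(self):
        labels = [m.label for m in enumerate_models(["a", "b", "c"])]
        assert labels == ["a+b+c", "a+b", "a+c", "b+c", "a", "b", "c"]

    def test_k_zero_and_cap(self):
        with pytest.raises(UsageError):
            enumerate_models([])
        with pytest.raises(UsageError, match="cap"):
            enumerate_models([f"p{i}" for i in range(17)])


class TestWeightedFit:
    def test_hand_solved_slope(self):
        # z = 0.25 y exactly: the normal equations give beta 0.25, alpha 0,
        # and the zero residual variance is flagged as degenerate
        with pytest.raises(DegenerateVarianceError) as excinfo:
            fit_weighted_lm(
                np.array([0, 0.25, 0.25, 0.5]),
                np.array([0.0, 1, 1, 2]),
                np.ones(4),
            )
        assert excinfo.value.betas[0] == pytest.approx(0.25)
        assert excinfo.value.alpha == pytest.approx(0.0, abs=1e-12)

    def test_hand_solved_slope_with_noise(self):
        # same configuration perturbed off the perfect fit: coefficients
        # stay at the hand-solved normal-equations solution of the data
        z = np.array([0.01, 0.24, 0.26, 0.49])
        y = np.array([0.0, 1, 1, 2])
        fit = fit_weighted_lm(z, y, np.ones(4))
        zbar, ybar = z.mean(), y.mean()
        beta_hand = np.sum((y - ybar) * (z - zbar)) / np.sum((y - ybar) ** 2)
        assert fit.betas[0] == pytest.approx(beta_hand)
        assert fit.alpha == pytest.approx(zbar - beta_hand * ybar)

    def test_unit_weights_reduce_to_ols(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=30)
        y = rng.normal(size=(30, 2))
        fit = fit_weighted_lm(z, y, np.ones(30))
        coef = np.linalg.lstsq(
            np.column_stack([np.ones(30), y]), z, rcond=None
        )[0]
        np.testing.assert_allclose(np.r_[fit.alpha, fit.betas], coef, rtol=1e-10)

    def test_constant_outcome_is_degenerate(self):
        with pytest.raises(DegenerateVarianceError):
            fit_weighted_lm(np.full(10, 0.3), np.arange(10.0), np.ones(10))

    def test_collinear_phenotypes_singular(self):
        y = np.arange(10.0)
        with pytest.raises(SingularModelError):
            fit_weighted_lm(
                np.random.default_rng(0).normal(size=10),
                np.column_stack([y, y]),
                np.ones(10),
            )

    def test_null_fit_is_weighted_mean(self):
        assert fit_null(
            np.array([0.0, 1.0]), np.array([1.0, 1.0])
        ).alpha == pytest.approx(0.5)
        assert fit_null(
            np.array([0.0, 1.0]), np.array([3.0, 1.0])
        ).alpha == pytest.approx(0.25)  # 3*0/4 + 1*1/4

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(8, 51))
            k = int(rng.integers(1, 4))
            z = rng.normal(size=n)
            y = rng.normal(size=(n, k))
            w = rng.integers(1, 30, size=n).astype(float)
            fit = fit_weighted_lm(z, y, w)
            coef, ses, loglik = wls_oracle(z, y, w)
            np.testing.assert_allclose(np.r_[fit.alpha, fit.betas], coef, rtol=1e-8)
            np.testing.assert_allclose(fit.ses, ses[1:], rtol=1e-8)
            assert fit.loglik == pytest.approx(loglik, rel=1e-8)

    def test_statsmodels_cross_check(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 40
        z = rng.normal(size=n)
        y = rng.normal(size=(n, 2))
        w = rng.integers(1, 20, size=n).astype(float)
        x = np.column_stack([np.ones(n), y])
        res = sm.WLS(z, x, weights=w).fit()
        fit = fit_weighted_lm(z, y, w)
        np.testing.assert_allclose(np.r_[fit.alpha, fit.betas], res.params, rtol=1e-10)
        np.testing.assert_allclose(fit.ses, res.bse[1:], rtol=1e-10)
        assert fit.loglik == pytest.approx(res.llf, rel=1e-10)

    def test_nesting_never_decreases_loglik(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = 25
            z = rng.normal(size=n)
            y = rng.normal(size=(n, 3))
            w = rng.integers(1, 10, size=n).astype(float)
            sub = fit_weighted_lm(z, y[:, :2], w)
            full = fit_weighted_lm(z, y, w)
            assert full.loglik >= sub.loglik - 1e-8

    def test_pvalue_invariant_to_constant_weight_scale(self):
        rng = np.random.default_rng(9)
        n = 30
        z = rng.normal(size=n)
        y = rng.normal(size=(n, 2))
        pvals = []
        for c in (1.0, 2.0, 17.5):
            w = np.full(n, c)
            fit = fit_weighted_lm(z, y, w)
            null = fit_null(z, w)
            pvals.append(lrt_pvalue(fit.loglik, null.loglik, 2))
        assert pvals[0] == pytest.approx(pvals[1], rel=1e-10)
        assert pvals[0] == pytest.approx(pvals[2], rel=1e-10)


class TestLrtAndBic:
    def test_equal_likelihoods_give_p_one(self):
        assert lrt_pvalue(-10.0, -10.0, 1) == 1.0

    def test_chi2_95th_percentile(self):
        assert lrt_pvalue(3.841 / 2, 0.0, 1) == pytest.approx(0.05, abs=1e-4)

    def test_p_increases_with_df_at_fixed_statistic(self):
        assert lrt_pvalue(2.0, 0.0, 4) > lrt_pvalue(2.0, 0.0, 1)

    def test_nesting_violation_raises(self):
        with pytest.raises(Exception, match="nested"):
            lrt_pvalue(-11.0, -10.0, 1)

    def test_bic_arithmetic(self):
        assert bic(0.0, 3, 1) == 0.0
        assert bic(-100.0, 3, 100) == pytest.approx(3 * math.log(100) + 200)

    def test_useless_parameter_adds_ln_n(self):
        assert bic(-5.0, 4, 50) - bic(-5.0, 3, 50) == pytest.approx(math.log(50))

    @pytest.mark.parametrize(
        "alpha, n, expected",
        [(0.05, 30000, "1.67e-06"), (0.05, 90000, "5.56e-07"), (0.05, 1, "5.00e-02")],
    )
    def test_bonferroni_threshold(self, alpha, n, expected):
        assert f"{bonferroni_threshold(alpha, n):.2e}" == expected


class TestAnalyseRegion:
    def test_complete_cases_shared_across_submodels(self):
        y = np.array([[1.0, 2.0], [1.0, np.nan], [0.0, 1.0], [2.0, 0.0],
                      [1.0, 1.0], [0.5, 0.5], [0.1, 0.9], [1.2, -0.4]])
        table = _table(y)
        bv = _burden(np.array([0.1, 0.2, 0.3, 0.1, 0.0, 0.2, 0.15, 0.05]),
                     np.array([2, 3, 2, 0, 4, 3, 2, 5]))
        mask = complete_cases(table, ["p1", "p2"], bv)
        # individual 1 missing p2 (excluded everywhere), individual 3 has n=0
        assert mask.tolist() == [True, False, True, False, True, True, True, True]

    def test_insufficient_sample_skips(self):
        table = _table(np.array([[1.0], [2.0], [3.0]]))
        bv = _burden(np.array([0.1, 0.2, 0.3]), np.array([1, 1, 0]))
        with pytest.raises(RegionSkipped, match="insufficient"):
            complete_cases(table, ["p1"], bv)

    def test_three_fits_for_two_phenotypes(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(40, 2))
        bv = _burden(rng.random(40) * 0.2, rng.integers(1, 10, 40))
        fits = analyse_region(bv, _table(y), ["p1", "p2"])
        assert [f.spec.label for f in fits] == ["p1+p2", "p1", "p2"]
        assert all(f.status == "ok" for f in fits)
        for f in fits:
            assert f.lrt_stat == pytest.approx(
                2 * (f.loglik - f.null_loglik), abs=1e-9
            )
            assert 0 < f.p_value <= 1

    def test_collinear_full_model_na_singletons_ok(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=30)
        y = np.column_stack([a, a])  # duplicated phenotype column
        bv = _burden(rng.random(30) * 0.2, rng.integers(1, 8, 30))
        fits = analyse_region(bv, _table(y), ["p1", "p2"])
        assert fits[0].status.startswith("singular")
        assert fits[1].status == "ok" and fits[2].status == "ok"

    def test_constant_burden_degenerate_everywhere(self):
        y = np.random.default_rng(6).normal(size=(20, 2))
        bv = _burden(np.full(20, 0.25), np.full(20, 4))
        fits = analyse_region(bv, _table(y), ["p1", "p2"])
        assert all(f.status == "degenerate variance" for f in fits)

    def test_best_bic_flagging(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=(60, 2))
        z = 0.1 + 0.05 * y[:, 0] + rng.normal(0, 0.02, 60)
        bv = _burden(np.clip(z, 0, 1), np.full(60, 10))
        fits = analyse_region(bv, _table(y), ["p1", "p2"])
        best = best_bic_fit(fits)
        assert best is not None
        assert best.bic == min(f.bic for f in fits if f.status == "ok")
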