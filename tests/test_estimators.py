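"""MR estimators: hand-checked values, algebraic identities, recovery."""

import math

import numpy as np
import pytest
from dataclasses import replace
from statsmodels.sandbox.regression.gmm import IV2SLS

from alcmr._regress import add_intercept, ols
from alcmr.config import default_scenario
from alcmr.estimators import ivw, mvmr, tsls_continuous, two_stage_binary, wald_ratio
from alcmr.instruments import first_stage
from alcmr.simulate import simulate_cohort


@pytest.fixture
def iv_fixture():
    """50-row deterministic one-sample IV dataset."""
    rng = np.random.default_rng(1234)
    n = 50
    z = rng.binomial(2, 0.4, n).astype(float)
    u = rng.normal(size=n)
    x = 0.8 * z + u + rng.normal(size=n)
    y = 0.5 * x + u + rng.normal(size=n)
    return y, x, z


class TestWaldRatio:
    def test_zero_numerator(self):
        est = wald_ratio(0.0, 0.1, 0.5, 0.05)
        assert est.beta == 0.0
        assert est.se == pytest.approx(0.1 / 0.5)

    def test_unit_denominator_identity(self):
        est = wald_ratio(0.37, 0.1, 1.0, 0.05)
        assert est.beta == 0.37

    def test_hand_value_first_and_second_order(self):
        est1 = wald_ratio(0.3, 0.1, 0.5, 0.05, se_method="first_order")
        assert est1.beta == pytest.approx(0.6)
        assert est1.se == pytest.approx(0.2)
        est2 = wald_ratio(0.3, 0.1, 0.5, 0.05, se_method="second_order")
        expected = math.sqrt(0.1**2 / 0.25 + 0.09 * 0.0025 / 0.0625)
        assert est2.se == pytest.approx(expected)
        assert est2.se == pytest.approx(0.20880613, abs=1e-7)

    def test_zero_denominator_is_explicit_error(self):
        with pytest.raises(ZeroDivisionError, match="weak"):
            wald_ratio(0.3, 0.1, 0.0, 0.05)

    def test_ci_is_beta_pm_1p96_se(self):
        est = wald_ratio(0.3, 0.1, 0.5, 0.05)
        assert est.ci95_low == pytest.approx(est.beta - 1.96 * est.se, abs=1e-3)
        assert est.ci95_high == pytest.approx(est.beta + 1.96 * est.se, abs=1e-3)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        est = ivw([0.5], [0.05], [0.3], [0.1])
        wald = wald_ratio(0.3, 0.1, 0.5, 0.05)
        assert est.beta == wald.beta
        assert est.se == wald.se

    def test_hand_value_two_snps(self):
        # ratios (0.5, 1.0) with weights (4, 1)
        est = ivw([2.0, 1.0], [0.1, 0.1], [1.0, 1.0], [1.0, 1.0])
        assert est.beta == pytest.approx(0.6)
        assert est.se == pytest.approx(1 / math.sqrt(5))
        assert est.q_statistic == pytest.approx(0.2)

    def test_equal_ratios_give_zero_q(self):
        est = ivw([1.0, 2.0, 0.5], [0.1] * 3, [0.7, 1.4, 0.35], [0.2] * 3)
        assert est.q_statistic == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(0.7)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(2)
        bgx = rng.normal(0.3, 0.05, 10)
        bgy = rng.normal(0.15, 0.02, 10)
        sgx, sgy = np.full(10, 0.03), np.full(10, 0.05)
        base = ivw(bgx, sgx, bgy, sgy)
        flip = np.array([1, -1] * 5)
        flipped = ivw(bgx * flip, sgx, bgy * flip, sgy)
        assert flipped.beta == pytest.approx(base.beta, rel=1e-12)
        assert flipped.q_statistic == pytest.approx(base.q_statistic, rel=1e-12)

    def test_random_effects_inflates_se_under_heterogeneity(self):
        bgx, sgx = [1.0, 1.0, 1.0], [0.01] * 3
        bgy, sgy = [0.1, 0.5, 0.9], [0.05] * 3
        fe = ivw(bgx, sgx, bgy, sgy)
        re = ivw(bgx, sgx, bgy, sgy, random_effects=True)
        assert re.se > fe.se
        assert re.beta == fe.beta

    def test_validation(self):
        with pytest.raises(ValueError):
            ivw([], [], [], [])
        with pytest.raises(ValueError):
            ivw([0.5], [0.0], [0.3], [0.1])
        with pytest.raises(ZeroDivisionError):
            ivw([0.0], [0.1], [0.3], [0.1])


class TestTSLS:
    def test_just_identified_equals_wald_of_reduced_form(self, iv_fixture):
        y, x, z = iv_fixture
        est = tsls_continuous(y, x, z)
        rf = first_stage(y, z)  # reduced form: outcome on instrument
        fs = first_stage(x, z)
        assert est.beta == pytest.approx(rf.beta_GX / fs.beta_GX, abs=1e-8)

    def test_matches_statsmodels_iv2sls(self, iv_fixture):
        y, x, z = iv_fixture
        est = tsls_continuous(y, x, z)
        ref = IV2SLS(y, add_intercept(x), add_intercept(z)).fit()
        assert est.beta == pytest.approx(ref.params[-1], rel=1e-8)
        assert est.se == pytest.approx(ref.bse[-1], rel=1e-6)

    def test_recovers_effect_under_confounding(self):
        sc = default_scenario(n_individuals=40_000)
        cohort, geno = simulate_cohort(sc, 77)
        dd = cohort["drinks_day"].to_numpy()
        y = cohort["sbp"].to_numpy()
        est = tsls_continuous(y, dd, geno.coded()[:, :1])
        assert abs(est.beta - 2.65) < 2 * est.se
        beta_ols, se_ols, _, _, _ = ols(y, add_intercept(dd))
        assert abs(beta_ols[-1] - 2.65) > 3 * se_ols[-1]  # naive estimate biased

    def test_weak_instrument_warning(self):
        rng = np.random.default_rng(3)
        n = 500
        z = rng.binomial(2, 0.3, n).astype(float)
        x = 0.01 * z + rng.normal(size=n)
        y = rng.normal(size=n)
        est = tsls_continuous(y, x, z)
        assert any("weak instrument" in w for w in est.warnings)

    def test_weak_instrument_bias_toward_ols_monotone_in_f(self):
        """One-sample 2SLS drifts toward the confounded OLS value as the
        first-stage F shrinks. Uses an over-identified design (15 weak
        instruments): just-identified 2SLS is approximately median-unbiased,
        so the classic toward-OLS drift appears with many instruments."""
        n, reps, k = 4_000, 120, 15
        var_noise = 2.0  # var(u) + var(e)
        mean_bias = {}
        for i, f_target in enumerate((5, 20, 100, 700)):
            r2 = k * f_target / (n + k * f_target)  # block F ~ n R^2/((1-R^2) k)
            gamma = math.sqrt(r2 * var_noise / (1 - r2) / (k * 0.42))
            ests = []
            for s in np.random.SeedSequence(100 + i).spawn(reps):
                rng = np.random.default_rng(s)
                Z = rng.binomial(2, 0.3, (n, k)).astype(float)
                u = rng.normal(size=n)
                x = gamma * Z.sum(axis=1) + u + rng.normal(size=n)
                y = 1.0 * u + rng.normal(size=n)  # true effect of x is zero
                ests.append(tsls_continuous(y, x, Z).beta)
            mean_bias[f_target] = float(np.mean(ests))
        assert mean_bias[5] > mean_bias[20] > mean_bias[100] > 0
        assert abs(mean_bias[700]) < abs(mean_bias[5]) / 5


class TestTwoStageBinary:
    def test_deterministic_exposure_matches_plain_logistic(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 20_000
        z = rng.binomial(2, 0.4, n).astype(float)
        x = 0.7 * z  # exposure fully determined by the instrument
        eta = -2.0 + 0.3 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        est = two_stage_binary(y, x, z)
        ref = sm.Logit(y, add_intercept(x)).fit(disp=0)
        assert abs(est.beta - ref.params[-1]) < 2 * est.se
        assert est.scale == "log_or"

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class|single-class"):
            two_stage_binary(np.zeros(100), np.ones(100), np.ones(100))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            two_stage_binary(np.arange(100, dtype=float), np.ones(100), np.ones(100))


class TestMVMR:
    def test_single_exposure_reduces_to_ivw(self):
        rng = np.random.default_rng(5)
        bgx = rng.normal(0.3, 0.05, 12)
        bgy = 0.5 * bgx + rng.normal(0, 0.01, 12)
        sgy = np.full(12, 0.02)
        res = mvmr(bgx, bgy, sgy, ("alcohol",))
        ref = ivw(bgx, np.full(12, 0.01), bgy, sgy)
        assert res.betas[0] == pytest.approx(ref.beta, rel=1e-12)
        assert res.ses[0] == pytest.approx(ref.se, rel=1e-12)

    def test_zero_column_is_informative_rank_error(self):
        bgx = np.column_stack([np.linspace(0.1, 0.5, 10), np.zeros(10)])
        with pytest.raises(ValueError, match="rank deficient"):
            mvmr(bgx, np.ones(10), np.full(10, 0.1), ("a", "b"))

    def test_direct_plus_mediated_recovery(self):
        rng = np.random.default_rng(6)
        m = 25
        b1 = rng.uniform(0.1, 0.4, m)
        b2 = rng.uniform(0.1, 0.4, m)
        sgy = np.full(m, 0.02)
        theta = (0.3, -0.2)
        bgy = theta[0] * b1 + theta[1] * b2 + rng.normal(0, 0.02, m)
        res = mvmr(np.column_stack([b1, b2]), bgy, sgy, ("alcohol", "bmi"))
        for i in range(2):
            assert abs(res.betas[i] - theta[i]) < 2 * res.ses[i]

    def test_more_exposures_than_snps_rejected(self):
        with pytest.raises(ValueError):
            mvmr(np.ones((1, 2)), np.ones(1), np.ones(1))


class TestCoverage:
    def test_ivw_ci_coverage_under_valid_instruments(self):
        """95% CIs bracket the truth in 93-97% of summary-level replicates."""
        theta = 0.4
        m, reps = 25, 600
        rng = np.random.default_rng(7)
        bgx_true = rng.uniform(0.2, 0.5, m)
        sgx, sgy = np.full(m, 0.02), np.full(m, 0.03)
        covered = 0
        for _ in range(reps):
            bgx_hat = bgx_true + rng.normal(0, sgx)
            bgy_hat = theta * bgx_true + rng.normal(0, sgy)
            est = ivw(bgx_hat, sgx, bgy_hat, sgy)
            covered += est.ci95_low <= theta <= est.ci95_high
        assert 0.93 <= covered / reps <= 0.97
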