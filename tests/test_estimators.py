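"""MR estimators against closed-form oracles, invariants, and simulations."""
import numpy as np
import pytest
from sklearn.base import clone

from mrmediate import (
    EggerEstimator,
    HarmonizedDataset,
    IVWEstimator,
    MaximumLikelihoodEstimator,
    SimulationConfig,
    WeightedMedianEstimator,
    egger,
    ivw,
    max_likelihood,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrmediate.exceptions import (
    InsufficientInstrumentsError,
    UndefinedRatioError,
)
from mrmediate.simulate import simulated_dataset


class TestWaldRatio:
    def test_direct_substitution(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_numerator(self):
        assert wald_ratio(0.2, 0.01, 0.0, 0.01).beta == 0.0

    def test_unit_denominator(self):
        est = wald_ratio(1.0, 0.01, 0.3, 0.2)
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.2)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(UndefinedRatioError):
            wald_ratio(0.0, 0.01, 0.1, 0.01)


def wls_through_origin(bx, by, sy):
    """Closed-form zero-intercept WLS oracle: beta and SE from X'WX."""
    w = 1.0 / np.asarray(sy) ** 2
    bx, by = np.asarray(bx), np.asarray(by)
    beta = np.sum(w * bx * by) / np.sum(w * bx**2)
    se = np.sum(w * bx**2) ** -0.5
    return beta, se


def wls_with_intercept(bx, by, sy):
    """Normal-equations oracle for the 2-parameter weighted regression."""
    w = np.diag(1.0 / np.asarray(sy) ** 2)
    x = np.column_stack([np.ones(len(bx)), bx])
    xtwx = x.T @ w @ x
    coef = np.linalg.solve(xtwx, x.T @ w @ np.asarray(by))
    cov_unscaled = np.linalg.inv(xtwx)
    return coef, cov_unscaled


class TestIVW:
    def test_single_snp_equals_wald(self):
        d = HarmonizedDataset.from_arrays([0.1], [0.01], [0.05], [0.02])
        est = ivw(d)
        ref = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_homogeneous_ratios(self):
        gamma = np.array([0.1, 0.2, 0.3])
        d = HarmonizedDataset.from_arrays(
            gamma, [0.01] * 3, 0.2 * gamma, [0.01, 0.02, 0.03]
        )
        fixed = ivw(d, mode="fixed")
        random = ivw(d, mode="random")
        assert fixed.beta == pytest.approx(0.2)
        assert fixed.q_stat == pytest.approx(0.0, abs=1e-20)
        assert random.se == pytest.approx(fixed.se)

    def test_matches_zero_intercept_wls(self, toy3):
        est = ivw(toy3, mode="fixed")
        beta, se = wls_through_origin(
            toy3.beta_exposure, toy3.beta_outcome, toy3.se_outcome
        )
        assert est.beta == pytest.approx(beta, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_equals_precision_weighted_mean_of_ratios(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            j = int(rng.integers(2, 30))
            bx = rng.uniform(0.05, 0.3, j) * rng.choice([-1, 1], j)
            by = rng.normal(0, 0.1, j)
            sy = rng.uniform(0.005, 0.05, j)
            d = HarmonizedDataset.from_arrays(bx, np.full(j, 0.01), by, sy)
            theta = by / bx
            w = bx**2 / sy**2
            assert ivw(d).beta == pytest.approx(
                np.sum(w * theta) / np.sum(w), abs=1e-12
            )

    def test_auto_mode_applies_heterogeneity_rule(self):
        # strongly heterogeneous ratios -> random effects, inflated SE
        d = HarmonizedDataset.from_arrays(
            [0.1, 0.1, 0.1, 0.1], [0.01] * 4,
            [0.01, 0.05, -0.04, 0.09], [0.005] * 4,
        )
        est = ivw(d, mode="auto")
        assert est.q_pval < 0.05
        assert est.method == "ivw_random"
        assert est.se > ivw(d, mode="fixed").se

    def test_random_se_never_below_fixed(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            j = 8
            d = HarmonizedDataset.from_arrays(
                rng.uniform(0.05, 0.2, j), np.full(j, 0.01),
                rng.normal(0, 0.02, j), rng.uniform(0.01, 0.03, j),
            )
            assert ivw(d, mode="random").se >= ivw(d, mode="fixed").se


class TestEgger:
    def test_noiseless_recovery(self, noiseless_factory):
        est = egger(noiseless_factory(0.5))
        assert est.beta == pytest.approx(0.5, abs=1e-9)
        assert est.intercept == pytest.approx(0.0, abs=1e-9)

    def test_outcome_translation_shifts_intercept_only(self, toy4):
        base = egger(toy4)
        shifted = HarmonizedDataset.from_arrays(
            toy4.beta_exposure, toy4.se_exposure,
            toy4.beta_outcome + 0.03, toy4.se_outcome,
        )
        est = egger(shifted)
        assert est.beta == pytest.approx(base.beta, abs=1e-10)
        assert est.intercept == pytest.approx(base.intercept + 0.03, abs=1e-10)

    def test_matches_normal_equations(self, toy4):
        est = egger(toy4)
        coef, cov = wls_with_intercept(
            toy4.beta_exposure, toy4.beta_outcome, toy4.se_outcome
        )
        resid = toy4.beta_outcome - (coef[0] + coef[1] * toy4.beta_exposure)
        q = float(np.sum((resid / toy4.se_outcome) ** 2))
        inflation = max(1.0, q / (toy4.n_snps - 2))
        assert est.beta == pytest.approx(coef[1], abs=1e-10)
        assert est.intercept == pytest.approx(coef[0], abs=1e-10)
        assert est.se == pytest.approx(
            np.sqrt(cov[1, 1] * inflation), abs=1e-10
        )
        assert est.q_stat == pytest.approx(q, abs=1e-10)

    def test_requires_three_instruments(self):
        d = HarmonizedDataset.from_arrays([0.1, 0.2], [0.01] * 2,
                                          [0.05, 0.1], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(d)


def brute_force_weighted_median(theta, w):
    """Independent oracle: interpolate the weighted empirical CDF at 1/2."""
    pairs = sorted(zip(theta, w))
    total = sum(p[1] for p in pairs)
    s = []
    running = 0.0
    for _, wi in pairs:
        s.append((running + wi / 2.0) / total)
        running += wi
    values = [p[0] for p in pairs]
    if 0.5 <= s[0]:
        return values[0]
    if 0.5 >= s[-1]:
        return values[-1]
    for k in range(1, len(s)):
        if s[k] >= 0.5:
            frac = (0.5 - s[k - 1]) / (s[k] - s[k - 1])
            return values[k - 1] + frac * (values[k] - values[k - 1])
    raise AssertionError("unreachable")


class TestWeightedMedian:
    def test_equal_weight_three_ratios(self):
        # ratios 0.1, 0.3, 0.9 with equal weights -> 0.3
        gamma = np.array([0.1, 0.1, 0.1])
        by = gamma * np.array([0.1, 0.3, 0.9])
        d = HarmonizedDataset.from_arrays(gamma, [0.01] * 3, by, [0.01] * 3)
        est = weighted_median(d, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.3)

    def test_constant_ratios_and_vanishing_noise(self):
        gamma = np.linspace(0.1, 0.3, 5)
        d = HarmonizedDataset.from_arrays(
            gamma, np.full(5, 1e-7), 0.4 * gamma, np.full(5, 1e-7)
        )
        est = weighted_median(d, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.4, abs=1e-6)
        assert est.se < 1e-5

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            j = int(rng.integers(3, 10))
            bx = rng.uniform(0.05, 0.3, j)
            by = rng.normal(0.05, 0.05, j)
            sy = rng.uniform(0.005, 0.05, j)
            d = HarmonizedDataset.from_arrays(bx, np.full(j, 0.01), by, sy)
            est = weighted_median(d, n_boot=2, seed=0)
            expected = brute_force_weighted_median(by / bx, bx**2 / sy**2)
            assert est.beta == pytest.approx(expected, abs=1e-12)

    def test_penalization_tames_planted_outlier(self):
        rng = np.random.default_rng(42)
        j = 10
        gamma = rng.uniform(0.1, 0.3, j)
        by = 0.2 * gamma + rng.normal(0, 0.002, j)
        by[0] = 0.2 * gamma[0] + 0.25  # wild outlier
        d = HarmonizedDataset.from_arrays(gamma, np.full(j, 0.005),
                                          by, np.full(j, 0.01))
        plain = weighted_median(d, n_boot=10, seed=0).beta
        pen = weighted_median(d, penalized=True, n_boot=10, seed=0).beta
        assert abs(pen - 0.2) <= abs(plain - 0.2)

    def test_bootstrap_se_reproducible(self, toy3):
        a = weighted_median(toy3, n_boot=300, seed=9)
        b = weighted_median(toy3, n_boot=300, seed=9)
        assert a.se == b.se


class TestMaximumLikelihood:
    def test_noiseless_recovery(self, noiseless_factory):
        est = max_likelihood(noiseless_factory(0.4))
        assert est.beta == pytest.approx(0.4, abs=1e-6)

    def test_single_snp_equals_wald(self):
        d = HarmonizedDataset.from_arrays([0.1, 0.12], [0.01] * 2,
                                          [0.05, 0.06], [0.02] * 2)
        ml = max_likelihood(d)
        # homogeneous two-SNP case: ML agrees with IVW closely
        assert ml.beta == pytest.approx(ivw(d).beta, abs=1e-4)

    def test_simulation_recovery_agrees_with_ivw(self):
        cfg = SimulationConfig(seed=123, n_snps=20, theta=0.3)
        d, truth = simulated_dataset(cfg)
        ml = max_likelihood(d)
        ref = ivw(d)
        assert abs(ml.beta - 0.3) < 3 * ml.se
        assert abs(ml.beta - ref.beta) < np.hypot(ml.se, ref.se)


class TestOddsRatioView:
    def test_paper_scale_transforms(self):
        # printed log-odds of ~0.278 and ~0.569 exponentiate to ORs near
        # 1.321 and 1.766 (both inputs independently rounded to 3 dp)
        assert np.exp(0.278) == pytest.approx(1.321, abs=1e-3)
        ov = to_odds_ratio(wald_ratio(1.0, 0.0001, 0.569, 0.23))
        assert ov.or_point == pytest.approx(1.766, abs=1e-3)

    def test_zero_beta_gives_unit_or(self):
        ov = to_odds_ratio(wald_ratio(1.0, 0.01, 0.0, 0.1))
        assert ov.or_point == 1.0

    def test_ci_order_preserved(self, toy3):
        est = ivw(toy3)
        ov = est.to_odds_ratio()
        assert ov.or_low < ov.or_point < ov.or_high
        assert ov.or_point == pytest.approx(np.exp(est.beta), rel=0)


class TestInvarianceProperties:
    def test_scale_equivariance(self, toy4):
        k = 3.7
        scaled = HarmonizedDataset.from_arrays(
            k * toy4.beta_exposure, k * toy4.se_exposure,
            toy4.beta_outcome, toy4.se_outcome,
        )
        for fn in (lambda d: ivw(d).beta,
                   lambda d: egger(d).beta,
                   lambda d: weighted_median(d, n_boot=2, seed=0).beta,
                   lambda d: max_likelihood(d).beta):
            assert fn(scaled) == pytest.approx(fn(toy4) / k, abs=1e-6)

    def test_antisymmetry_under_outcome_negation(self, toy4):
        neg = HarmonizedDataset.from_arrays(
            toy4.beta_exposure, toy4.se_exposure,
            -toy4.beta_outcome, toy4.se_outcome,
        )
        assert ivw(neg).beta == pytest.approx(-ivw(toy4).beta, abs=1e-12)
        e_pos, e_neg = egger(toy4), egger(neg)
        assert e_neg.beta == pytest.approx(-e_pos.beta, abs=1e-12)
        assert e_neg.intercept == pytest.approx(-e_pos.intercept, abs=1e-12)
        assert max_likelihood(neg).beta == pytest.approx(
            -max_likelihood(toy4).beta, abs=1e-6
        )

    def test_all_estimators_agree_noiselessly(self, noiseless_factory):
        d = noiseless_factory(0.25)
        estimates = [
            ivw(d).beta,
            egger(d).beta,
            weighted_median(d, n_boot=2, seed=0).beta,
            weighted_median(d, penalized=True, n_boot=2, seed=0).beta,
            max_likelihood(d).beta,
        ]
        np.testing.assert_allclose(estimates, 0.25, atol=1e-6)


class TestSklearnSurface:
    def test_get_set_params_and_clone(self):
        est = WeightedMedianEstimator(penalized=True, n_boot=50, random_state=4)
        cloned = clone(est)
        assert cloned.get_params()["penalized"] is True
        assert cloned.get_params()["n_boot"] == 50

    def test_fit_predict_shapes(self, toy4):
        model = IVWEstimator().fit(
            toy4.beta_exposure, toy4.beta_outcome,
            outcome_se=toy4.se_outcome,
        )
        pred = model.predict(toy4.beta_exposure)
        assert pred.shape == (4,)
        np.testing.assert_allclose(pred, model.beta_ * toy4.beta_exposure)

    @pytest.mark.parametrize("cls", [IVWEstimator, EggerEstimator,
                                     MaximumLikelihoodEstimator])
    def test_column_vector_inputs_accepted(self, cls, toy4):
        model = cls().fit(
            toy4.beta_exposure.reshape(-1, 1), toy4.beta_outcome,
            exposure_se=toy4.se_exposure, outcome_se=toy4.se_outcome,
        )
        assert np.isfinite(model.beta_)
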