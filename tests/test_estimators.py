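"""Model fitting, contrasts, and estimand routing."""

import math

import numpy as np
import pandas as pd
import pytest

from factorial_estimands import (
    CellParams,
    EstimandSpec,
    FitError,
    Measure,
    ModelKind,
    OutcomeType,
    SimulationConfig,
    Strategy,
    Target,
    TrialDataset,
    conditional_effect,
    estimate_estimand,
    fit_model,
    interaction_assessment,
    linear_combination,
    simulate_factorial,
    weighted_usual_practice,
)

from conftest import (
    TABLE_CELLS,
    balanced_binary_dataset,
    balanced_continuous_dataset,
    cells_with_logodds_interaction,
)


class TestFitModel:
    def test_noiseless_additive_factorial_fit_is_exact(self, noiseless_additive_data):
        fit = fit_model(
            noiseless_additive_data, ModelKind.FACTORIAL_ADJUSTED, Measure.MEAN_DIFFERENCE
        )
        assert fit.coef["beta_a"] == pytest.approx(1.0, abs=1e-10)
        assert fit.coef["beta_b"] == pytest.approx(2.0, abs=1e-10)

    def test_noiseless_additive_interaction_is_zero(self, noiseless_additive_data):
        fit = fit_model(noiseless_additive_data, ModelKind.INTERACTION, Measure.MEAN_DIFFERENCE)
        assert fit.coef["beta_int"] == pytest.approx(0.0, abs=1e-10)

    def test_adjusted_logistic_recovers_conditional_log_or(self):
        """Large balanced binary data: beta_a within 3 SE of the oracle."""
        data = balanced_binary_dataset(TABLE_CELLS, n_per_cell=20_000, seed=11)
        fit = fit_model(data, ModelKind.FACTORIAL_ADJUSTED, Measure.ODDS_RATIO)
        se = math.sqrt(fit.vcov[fit.names.index("beta_a"), fit.names.index("beta_a")])
        truth = math.log(conditional_effect(TABLE_CELLS, 0, Measure.ODDS_RATIO))
        assert abs(fit.coef["beta_a"] - truth) < 3 * se

    def test_multiarm_requires_all_cells(self):
        rows = [(0, 0, 1.0), (1, 0, 0.0), (1, 1, 1.0)]
        data = TrialDataset(
            df=pd.DataFrame(rows, columns=["z_a", "z_b", "y"]),
            outcome_type=OutcomeType.BINARY,
        )
        with pytest.raises(FitError, match="multiarm"):
            fit_model(data, ModelKind.MULTIARM, Measure.ODDS_RATIO)

    def test_separation_raises_named_error(self):
        # every (1,1) outcome is an event -> infinite cell log-odds
        rows = (
            [(0, 0, float(i % 2)) for i in range(10)]
            + [(1, 0, float(i % 2)) for i in range(10)]
            + [(0, 1, float(i % 2)) for i in range(10)]
            + [(1, 1, 1.0)] * 10
        )
        data = TrialDataset(
            df=pd.DataFrame(rows, columns=["z_a", "z_b", "y"]),
            outcome_type=OutcomeType.BINARY,
        )
        with pytest.raises(FitError):
            fit_model(data, ModelKind.MULTIARM, Measure.ODDS_RATIO)

    def test_measure_outcome_mismatch_rejected(self, noiseless_additive_data):
        with pytest.raises(ValueError):
            fit_model(noiseless_additive_data, ModelKind.MULTIARM, Measure.ODDS_RATIO)

    def test_risk_difference_uses_sandwich_covariance(self):
        """Identity-link LS on 0/1 outcomes: coefficient equals the cell-risk
        contrast and the robust SE matches the binomial variance formula."""
        data = balanced_binary_dataset(TABLE_CELLS, n_per_cell=5_000, seed=21)
        fit = fit_model(data, ModelKind.MULTIARM, Measure.RISK_DIFFERENCE)
        y = data.df["y"].to_numpy()
        cells = {
            (a, b): y[data.cell_mask(a, b)] for a in (0, 1) for b in (0, 1)
        }
        p00, p10 = cells[(0, 0)].mean(), cells[(1, 0)].mean()
        assert fit.coef["beta_a0"] == pytest.approx(p10 - p00, abs=1e-10)
        idx = fit.names.index("beta_a0")
        expected_var = p00 * (1 - p00) / len(cells[(0, 0)]) + p10 * (1 - p10) / len(
            cells[(1, 0)]
        )
        assert fit.vcov[idx, idx] == pytest.approx(expected_var, rel=0.02)


class TestLinearCombination:
    def test_identity_weights_reproduce_coefficient(self, noiseless_interaction_data):
        data = balanced_continuous_dataset((0.0, 1.0, 2.0, 5.0), 10, sigma=1.0, seed=5)
        fit = fit_model(data, ModelKind.FACTORIAL_ADJUSTED, Measure.MEAN_DIFFERENCE)
        est = linear_combination(fit, {"beta_a": 1.0})
        idx = fit.names.index("beta_a")
        assert est.estimate_link == pytest.approx(fit.coef["beta_a"], rel=1e-15)
        assert est.se_link == pytest.approx(math.sqrt(fit.vcov[idx, idx]), rel=1e-12)

    def test_multiarm_contrast_on_noiseless_data(self, noiseless_interaction_data):
        fit = fit_model(noiseless_interaction_data, ModelKind.MULTIARM, Measure.MEAN_DIFFERENCE)
        est = linear_combination(fit, {"beta_ab": 1.0, "beta_0b": -1.0})
        assert est.estimate_link == pytest.approx(3.0, abs=1e-10)

    def test_unknown_coefficient_name_rejected(self, noiseless_additive_data):
        fit = fit_model(
            noiseless_additive_data, ModelKind.FACTORIAL_ADJUSTED, Measure.MEAN_DIFFERENCE
        )
        with pytest.raises(ValueError, match="beta_zz"):
            linear_combination(fit, {"beta_zz": 1.0})

    def test_contrast_variance_matches_bootstrap(self):
        """Delta-method variance of the beta_ab - beta_0b contrast — which
        needs the off-diagonal covariance — vs a 500-resample nonparametric
        bootstrap, within 15% relative error.  The saturated logistic model
        is used so the model-based and bootstrap variances estimate the
        same quantity."""
        rng = np.random.default_rng(123)
        cells = CellParams(0.3, 0.45, 0.5, 0.6)
        data = balanced_binary_dataset(cells, n_per_cell=250, seed=7)
        fit = fit_model(data, ModelKind.MULTIARM, Measure.ODDS_RATIO)
        est = linear_combination(fit, {"beta_ab": 1.0, "beta_0b": -1.0})
        n = len(data)
        boot = []
        df = data.df
        for _ in range(500):
            idx = rng.integers(0, n, size=n)
            resampled = TrialDataset(
                df=df.iloc[idx].reset_index(drop=True), outcome_type=OutcomeType.BINARY
            )
            bfit = fit_model(resampled, ModelKind.MULTIARM, Measure.ODDS_RATIO)
            boot.append(bfit.coef["beta_ab"] - bfit.coef["beta_0b"])
        boot_var = float(np.var(boot, ddof=1))
        assert est.se_link**2 == pytest.approx(boot_var, rel=0.15)

    def test_natural_ci_is_exp_of_link_ci(self):
        data = balanced_binary_dataset(TABLE_CELLS, n_per_cell=500, seed=4)
        fit = fit_model(data, ModelKind.FACTORIAL_ADJUSTED, Measure.ODDS_RATIO)
        est = linear_combination(fit, {"beta_a": 1.0})
        assert est.ci_low_natural == math.exp(est.ci_low)
        assert est.ci_high_natural == math.exp(est.ci_high)
        assert est.ci_low <= est.estimate_link <= est.ci_high


class TestEstimateEstimand:
    def test_multiarm_routes_per_target_on_noiseless_data(self, noiseless_interaction_data):
        cases = {
            Target.A_GIVEN_NO_B: 1.0,
            Target.A_GIVEN_B: 3.0,
            Target.A_PLUS_B: 5.0,
        }
        for target, expected in cases.items():
            est = estimate_estimand(
                noiseless_interaction_data,
                EstimandSpec(target, Measure.MEAN_DIFFERENCE),
                Strategy.MULTIARM,
            )
            assert est.estimate_link == pytest.approx(expected, abs=1e-10)

    def test_factorial_combination_is_sum_of_main_effects(self, noiseless_additive_data):
        est = estimate_estimand(
            noiseless_additive_data,
            EstimandSpec(Target.A_PLUS_B, Measure.MEAN_DIFFERENCE),
            Strategy.FACTORIAL,
        )
        assert est.estimate_link == pytest.approx(3.0, abs=1e-10)

    def test_multiarm_a_given_b_consistent_for_log_or(self):
        data = balanced_binary_dataset(TABLE_CELLS, n_per_cell=20_000, seed=31)
        est = estimate_estimand(
            data, EstimandSpec(Target.A_GIVEN_B, Measure.ODDS_RATIO), Strategy.MULTIARM
        )
        truth = math.log(conditional_effect(TABLE_CELLS, 1, Measure.ODDS_RATIO))
        assert abs(est.estimate_link - truth) < 3 * est.se_link

    def test_marginal_or_usual_practice_flagged_as_unavailable(self):
        data = balanced_binary_dataset(TABLE_CELLS, n_per_cell=200, seed=2)
        spec = EstimandSpec(Target.A_USUAL_PRACTICE, Measure.ODDS_RATIO, pi=0.5)
        est = estimate_estimand(data, spec, Strategy.MULTIARM)
        assert est.note is not None and "no unbiased estimator" in est.note


class TestWeightedUsualPractice:
    @pytest.mark.parametrize(
        "pi,expected", [(0.0, 1.0), (1.0, 3.0), (0.5, 2.0)], ids=["pi0", "pi1", "pi_half"]
    )
    def test_weighted_contrast_on_noiseless_data(
        self, noiseless_interaction_data, pi, expected
    ):
        fit = fit_model(noiseless_interaction_data, ModelKind.MULTIARM, Measure.MEAN_DIFFERENCE)
        est = weighted_usual_practice(fit, pi)
        assert est.estimate_link == pytest.approx(expected, abs=1e-10)

    def test_degenerate_weights_match_plain_contrasts_exactly(
        self, noiseless_interaction_data
    ):
        data = balanced_continuous_dataset((0.0, 1.0, 2.0, 5.0), 25, sigma=1.0, seed=13)
        fit = fit_model(data, ModelKind.MULTIARM, Measure.MEAN_DIFFERENCE)
        at0 = weighted_usual_practice(fit, 0.0)
        plain0 = linear_combination(fit, {"beta_a0": 1.0})
        assert (at0.estimate_link, at0.se_link) == (plain0.estimate_link, plain0.se_link)
        at1 = weighted_usual_practice(fit, 1.0)
        plain1 = linear_combination(fit, {"beta_ab": 1.0, "beta_0b": -1.0})
        assert (at1.estimate_link, at1.se_link) == (plain1.estimate_link, plain1.se_link)

    def test_requires_multiarm_fit(self, noiseless_additive_data):
        fit = fit_model(
            noiseless_additive_data, ModelKind.FACTORIAL_ADJUSTED, Measure.MEAN_DIFFERENCE
        )
        with pytest.raises(ValueError):
            weighted_usual_practice(fit, 0.5)


class TestInteractionAssessment:
    def test_noiseless_additive_interaction_null(self, noiseless_additive_data):
        est = interaction_assessment(noiseless_additive_data, Measure.MEAN_DIFFERENCE)
        assert est.estimate_link == pytest.approx(0.0, abs=1e-10)
        assert est.p_value == pytest.approx(1.0)

    def test_null_interaction_z_statistic_is_moderate_at_large_n(self):
        data = balanced_binary_dataset(TABLE_CELLS, n_per_cell=50_000, seed=17)
        est = interaction_assessment(data, Measure.ODDS_RATIO)
        # the rounded cell probabilities carry a tiny real interaction, so
        # |z| is not forced to be < 2, but it stays moderate
        assert abs(est.estimate_link / est.se_link) < 4

    def test_interaction_test_power_at_unit_log_or(self):
        """Log-OR interaction of 1.0, n = 5,000/cell: rejection at the 5%
        level in >90% of 200 replicates."""
        cells = cells_with_logodds_interaction(0.5, 0.333, 0.091, delta=1.0)
        rejections = 0
        for r in range(200):
            data = balanced_binary_dataset(cells, n_per_cell=5_000, seed=1_000 + r)
            est = interaction_assessment(data, Measure.ODDS_RATIO)
            rejections += est.p_value < 0.05
        assert rejections / 200 > 0.90


class TestReparameterization:
    def test_interaction_model_reparameterizes_multiarm(self):
        """beta_a0 = beta_a, beta_0b = beta_b, beta_ab = beta_a + beta_b +
        beta_int, with matching contrast variances."""
        data = balanced_binary_dataset(TABLE_CELLS, n_per_cell=400, seed=77)
        ma = fit_model(data, ModelKind.MULTIARM, Measure.ODDS_RATIO)
        im = fit_model(data, ModelKind.INTERACTION, Measure.ODDS_RATIO)
        assert ma.coef["beta_a0"] == pytest.approx(im.coef["beta_a"], abs=1e-6)
        assert ma.coef["beta_0b"] == pytest.approx(im.coef["beta_b"], abs=1e-6)
        assert ma.coef["beta_ab"] == pytest.approx(
            im.coef["beta_a"] + im.coef["beta_b"] + im.coef["beta_int"], abs=1e-6
        )
        sum_con = linear_combination(im, {"beta_a": 1, "beta_b": 1, "beta_int": 1})
        ab = linear_combination(ma, {"beta_ab": 1})
        assert sum_con.se_link == pytest.approx(ab.se_link, abs=1e-6)
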