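"""Parametric g-formula: fitting restrictions, simulation, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from gswitch.discrete_survival import FitFailure
from gswitch.gformula import (
    GFormulaSpec,
    CovariateModel,
    add_lag_columns,
    default_gformula_spec,
    fit_gformula_models,
    gformula_effects,
    natural_course_check,
    screen_gformula_spec,
    simulate_counterfactual,
)
from gswitch.core_data import TermSpec
from gswitch.synthetic_trial import default_config, generate_person_time, null_config


@pytest.fixture(scope="module")
def fitted_control(medium_cohort_table):
    spec = default_gformula_spec(n_simulated=4000, horizon=48)
    models = fit_gformula_models(medium_cohort_table, spec, arm=0)
    baseline = medium_cohort_table.loc[
        (medium_cohort_table["arm"] == 0) & (medium_cohort_table["k"] == 0)
    ]
    return spec, models, baseline


def test_spec_rejects_forward_reference():
    with pytest.raises(ValueError, match="before it is simulated"):
        GFormulaSpec(
            covariate_models=(
                CovariateModel(
                    "dp", "binary-logistic", (TermSpec("tls"),)
                ),
                CovariateModel("tls", "linear-gaussian", ()),
            ),
            outcome_terms=(),
        )


def test_lag_columns_shift_within_subject(small_cohort_table):
    work = add_lag_columns(small_cohort_table)
    one = work.loc[work["subject_id"] == work["subject_id"].iloc[0]]
    np.testing.assert_array_equal(
        one["lag_tls"].to_numpy()[1:], one["tls"].to_numpy()[:-1]
    )
    assert one["lag_dp"].iloc[0] == 0
    assert one["lag_treatment"].iloc[0] == one["arm"].iloc[0]


class TestFitting:
    def test_absorbing_models_fit_only_on_lagged_zero(self, medium_cohort_table):
        work = add_lag_columns(
            medium_cohort_table.loc[medium_cohort_table["arm"] == 0]
        )
        eligible = work.loc[(work["k"] >= 1) & (work["lag_dp"] == 0)]
        spec = default_gformula_spec()
        models = fit_gformula_models(medium_cohort_table, spec, arm=0)
        assert models.covariate_fits["dp"].n_obs == len(eligible)

    def test_outcome_model_never_sees_pre_progression_rows(self, medium_cohort_table):
        spec = default_gformula_spec()
        models = fit_gformula_models(medium_cohort_table, spec, arm=0)
        at_risk = medium_cohort_table.loc[
            (medium_cohort_table["arm"] == 0) & (medium_cohort_table["dp"] == 1)
        ]
        assert models.outcome_fit.n_obs == len(at_risk)

    def test_linear_gaussian_residual_sd_matches_direct_computation(
        self, medium_cohort_table
    ):
        spec = default_gformula_spec()
        models = fit_gformula_models(medium_cohort_table, spec, arm=0)
        fit = models.covariate_fits["tls"]
        work = add_lag_columns(
            medium_cohort_table.loc[medium_cohort_table["arm"] == 0]
        )
        rows = work.loc[work["k"] >= 1]
        resid = rows["tls"].to_numpy() - fit.predict(rows)
        dof = len(rows) - len(fit.params)
        assert fit.resid_sd == pytest.approx(
            np.sqrt(resid @ resid / dof), rel=1e-9
        )

    def test_constant_treatment_dropped_in_experimental_arm(
        self, medium_cohort_table
    ):
        spec = default_gformula_spec()
        models = fit_gformula_models(medium_cohort_table, spec, arm=1)
        assert "treatment" in models.dropped_terms.get("outcome", [])

    def test_empty_arm_raises(self, medium_cohort_table):
        t = medium_cohort_table.loc[medium_cohort_table["arm"] == 0]
        with pytest.raises(FitFailure):
            fit_gformula_models(t, default_gformula_spec(), arm=1)


class TestSimulation:
    def test_absorbing_restriction_holds_in_simulated_means(self, fitted_control):
        spec, models, baseline = fitted_control
        res = simulate_counterfactual(models, baseline, "always_control", seed=5,
                                      n_simulated=3000)
        dp_means = res.covariate_means["dp"].to_numpy()
        assert np.all(np.diff(dp_means[~np.isnan(dp_means)]) >= -0.05)
        assert res.audit["risk_non_decreasing"]
        assert res.audit["treatment_forced"]

    def test_unknown_strategy_rejected(self, fitted_control):
        spec, models, baseline = fitted_control
        with pytest.raises(ValueError, match="unknown strategy"):
            simulate_counterfactual(models, baseline, "always_placebo", seed=1)

    def test_same_seed_reproducible(self, fitted_control):
        spec, models, baseline = fitted_control
        a = simulate_counterfactual(models, baseline, "always_control", seed=9,
                                    n_simulated=2000)
        b = simulate_counterfactual(models, baseline, "always_control", seed=9,
                                    n_simulated=2000)
        np.testing.assert_array_equal(a.risk, b.risk)

    def test_null_generator_gives_equal_strategy_curves(self):
        """With treatment absent from every transition, the two sustained
        strategies' simulated risks agree up to Monte-Carlo error."""
        cfg = null_config(n_control=400, n_experimental=0, seed=33)
        table = generate_person_time(cfg)
        spec = default_gformula_spec(n_simulated=8000)
        models = fit_gformula_models(table, spec, arm=0)
        r0 = simulate_counterfactual(
            models, table.loc[table["k"] == 0], "always_control", seed=1
        )
        r1 = simulate_counterfactual(
            models, table.loc[table["k"] == 0], "always_experimental", seed=1
        )
        se = np.sqrt(r0.mc_se(48) ** 2 + r1.mc_se(48) ** 2)
        # treatment coefficient is estimated (near 0), adding fit noise:
        # allow a generous but finite band
        assert abs(r0.risk_at(48) - r1.risk_at(48)) < max(6 * se, 0.05)


class TestNaturalCourse:
    def test_observed_column_equals_direct_averages(self, medium_cohort_table):
        spec = default_gformula_spec(horizon=24)
        models = fit_gformula_models(medium_cohort_table, spec, arm=0)
        check = natural_course_check(models, medium_cohort_table, seed=3,
                                     n_simulated=4000)
        arm0 = medium_cohort_table.loc[medium_cohort_table["arm"] == 0]
        row = check.loc[(check["month"] == 6) & (check["quantity"] == "tls")].iloc[0]
        direct = arm0.loc[arm0["k"] == 6, "tls"].mean()
        assert row["observed"] == pytest.approx(direct)

    def test_zero_tolerance_fails_somewhere(self, medium_cohort_table):
        spec = default_gformula_spec(horizon=24)
        models = fit_gformula_models(medium_cohort_table, spec, arm=0)
        check = natural_course_check(
            models, medium_cohort_table, seed=3, n_simulated=2000, se_multiple=0.0
        )
        assert (~check["ok"]).any()


class TestEffects:
    def test_identical_results_give_unit_ratios(self, fitted_control):
        spec, models, baseline = fitted_control
        r = simulate_counterfactual(models, baseline, "always_control", seed=2,
                                    n_simulated=2000)
        eff = gformula_effects(r, r, horizon=48)
        assert eff.rr == pytest.approx(1.0)
        assert eff.chr == pytest.approx(1.0)

    def test_rr_is_direct_ratio_of_stored_curves(self, fitted_control):
        spec, models, baseline = fitted_control
        r0 = simulate_counterfactual(models, baseline, "always_control", seed=2,
                                     n_simulated=2000)
        r1 = simulate_counterfactual(models, baseline, "always_experimental",
                                     seed=3, n_simulated=2000)
        eff = gformula_effects(r0, r1, horizon=48)
        assert eff.rr == pytest.approx(r1.risk[47] / r0.risk[47])

    def test_printed_risk_pair_ratio(self):
        """Counterfactual risks 0.41 and 0.56 at the horizon imply an RR of
        about 0.73 — the internal-consistency arithmetic check."""
        from gswitch.discrete_survival import SurvivalCurve, effect_estimates

        c = SurvivalCurve.from_risk(np.linspace(0.01, 0.56, 48))
        e = SurvivalCurve.from_risk(np.linspace(0.01, 0.41, 48))
        eff = effect_estimates(c, e, horizon=48)
        assert eff.rr == pytest.approx(0.41 / 0.56, rel=1e-12)
        assert round(eff.rr, 2) == 0.73


def test_screening_keeps_autoregressive_lags(medium_cohort_table):
    spec = default_gformula_spec()
    screened = screen_gformula_spec(medium_cohort_table, spec, arm=0,
                                    p_threshold=0.2)
    tls_model = [m for m in screened.covariate_models if m.name == "tls"][0]
    assert "lag_tls" in [t.name for t in tls_model.terms]
    # screening can only remove terms
    for cm_full, cm_scr in zip(spec.covariate_models, screened.covariate_models):
        assert set(t.name for t in cm_scr.terms) <= set(t.name for t in cm_full.terms)
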