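"""IPC weight construction, diagnostics, truncation and screening."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from gswitch.core_data import TermSpec, expand_to_person_time
from gswitch.discrete_survival import FitFailure
from gswitch.synthetic_trial import SwitchingHazard, default_config, generate_person_time
from gswitch.weighting import (
    WeightSeries,
    WeightSpec,
    combine_weights,
    compute_weights,
    fit_weight_models,
    ltfu_spec_default,
    screen_covariates,
    switching_spec_dropped_tdp,
    switching_spec_full,
    truncate_weights,
    weight_diagnostics,
)

from conftest import make_subject


@pytest.fixture(scope="module")
def fitted_switch(medium_cohort_table):
    spec = switching_spec_full()
    models = fit_weight_models(medium_cohort_table, spec)
    weights = compute_weights(models, medium_cohort_table)
    return spec, models, weights


class TestFitWeightModels:
    def test_no_progression_means_empty_eligible_set(self):
        subjects = [make_subject(f"s{i}", max_followup_months=12) for i in range(20)]
        table = expand_to_person_time(subjects, 12)
        with pytest.raises(FitFailure, match="empty eligible|no events"):
            fit_weight_models(table, switching_spec_full())

    def test_intercept_only_denominator_matches_event_rate(self, medium_cohort_table):
        spec = WeightSpec(
            target="switching",
            denominator_terms=(),
            numerator_terms=(),
            label="intercept-only",
        )
        models = fit_weight_models(medium_cohort_table, spec)
        t = medium_cohort_table
        elig = t.loc[(t["arm"] == 0) & (t["dp"] == 1)]
        # eligible set: post-progression rows up to and including the switch row
        first_switch = elig.groupby("subject_id")["switched"].cumsum() <= 1
        elig = elig.loc[first_switch]
        n_events = (
            elig.groupby("subject_id")["switched"].max().sum()
        )
        expected = n_events / len(elig)
        p = models.denominator[0].predict(elig.iloc[[0]])[0]
        assert p == pytest.approx(expected, rel=1e-6)

    def test_full_specification_produces_expected_coefficient_blocks(
        self, fitted_switch
    ):
        _, models, _ = fitted_switch
        labels = models.denominator[0].labels
        for expected in ("age", "tls", "tdp", "tdp^2", "k", "ecog_tv[1]",
                         "strata[1]", "diagnosis_stage[1]", "lung_involvement[1]",
                         "smoking[1]", "ics[1]"):
            assert expected in labels


class TestComputeWeights:
    def test_experimental_arm_weight_is_one_everywhere(self, fitted_switch):
        _, _, weights = fitted_switch
        exp_rows = weights.frame.loc[weights.frame["subject_id"].str.startswith("E")]
        np.testing.assert_allclose(exp_rows["stabilized"], 1.0)
        np.testing.assert_allclose(exp_rows["unstabilized"], 1.0)

    def test_pre_progression_weight_is_one(self, fitted_switch, medium_cohort_table):
        _, _, weights = fitted_switch
        merged = medium_cohort_table.merge(
            weights.frame, on=["subject_id", "k"], how="inner"
        )
        pre = merged.loc[(merged["arm"] == 0) & (merged["dp"] == 0)]
        assert len(pre) > 0
        np.testing.assert_allclose(pre["stabilized"], 1.0)

    def test_event_person_time_excluded(self, fitted_switch, medium_cohort_table):
        _, _, weights = fitted_switch
        merged = medium_cohort_table.merge(
            weights.frame, on=["subject_id", "k"], how="inner"
        )
        assert (merged["switched"] == 0).all()

    def test_hand_computed_cumulative_product(self):
        """Denominator switch probabilities (0.2, 0.25) and numerator
        (0.1, 0.1) over two post-progression intervals give stabilized
        (0.9/0.8)*(0.9/0.75) = 1.35 and unstabilized 1/(0.8*0.75)."""
        table = expand_to_person_time(
            [make_subject("a", progression_month=0, max_followup_months=2)], 2
        )

        class Stub:
            def __init__(self, probs):
                self.probs = probs
                self.converged = True

            def predict(self, df):
                return np.array([self.probs[int(k)] for k in df["k"]])

        from gswitch.weighting import WeightModelSet

        spec = switching_spec_full()
        models = WeightModelSet(
            spec=spec,
            numerator={0: Stub({0: 0.1, 1: 0.1})},
            denominator={0: Stub({0: 0.2, 1: 0.25})},
        )
        ws = compute_weights(models, table, spec)
        np.testing.assert_allclose(
            ws.frame["stabilized"], [0.9 / 0.8, (0.9 / 0.8) * (0.9 / 0.75)]
        )
        np.testing.assert_allclose(
            ws.frame["unstabilized"], [1 / 0.8, 1 / (0.8 * 0.75)]
        )

    def test_identical_numerator_and_denominator_gives_unit_weights(
        self, medium_cohort_table
    ):
        spec = WeightSpec(
            target="switching",
            denominator_terms=(TermSpec("k", "time_varying", "linear"),),
            numerator_terms=(TermSpec("k", "time_varying", "linear"),),
            label="degenerate",
        )
        models = fit_weight_models(medium_cohort_table, spec)
        ws = compute_weights(models, medium_cohort_table)
        np.testing.assert_allclose(ws.frame["stabilized"], 1.0, atol=1e-10)

    def test_non_anticipation(self, medium_cohort_table):
        """Deleting all rows with k > 12 leaves weights at k <= 12 unchanged."""
        spec = switching_spec_full()
        full_models = fit_weight_models(medium_cohort_table, spec)
        ws_full = compute_weights(full_models, medium_cohort_table)
        truncated = medium_cohort_table.loc[medium_cohort_table["k"] <= 12]
        ws_trunc = compute_weights(full_models, truncated, spec)
        merged = ws_trunc.frame.merge(
            ws_full.frame, on=["subject_id", "k"], suffixes=("_t", "_f")
        )
        np.testing.assert_allclose(
            merged["stabilized_t"], merged["stabilized_f"], rtol=1e-10
        )


class TestCombineAndTruncate:
    def test_combining_with_unit_weights_is_identity(self, fitted_switch):
        _, _, a = fitted_switch
        ones = WeightSeries(
            frame=a.frame.assign(stabilized=1.0, unstabilized=1.0), target="ltfu_ac"
        )
        combined = combine_weights(a, ones)
        np.testing.assert_allclose(combined.frame["stabilized"], a.frame["stabilized"])

    def test_self_product_squares_weights(self, fitted_switch):
        _, _, a = fitted_switch
        squared = combine_weights(a, a)
        np.testing.assert_allclose(
            squared.frame["stabilized"], a.frame["stabilized"] ** 2
        )

    def test_product_diagnostics_match_loop_oracle(self, fitted_switch):
        _, _, a = fitted_switch
        b = WeightSeries(frame=a.frame.copy(), target="ltfu_ac")
        combined = combine_weights(a, b)
        d = weight_diagnostics(combined)
        values = [
            wa * wb
            for wa, wb in zip(a.frame["stabilized"], b.frame["stabilized"])
        ]
        assert d.mean == pytest.approx(np.mean(values))
        assert d.sd == pytest.approx(np.std(values, ddof=1))

    def test_truncation_identity_at_full_range(self, fitted_switch):
        _, _, ws = fitted_switch
        out = truncate_weights(ws, 0, 100)
        np.testing.assert_allclose(out.frame["stabilized"], ws.frame["stabilized"])

    def test_truncation_at_median_gives_constant_weights(self, fitted_switch):
        _, _, ws = fitted_switch
        out = truncate_weights(ws, 50, 50)
        assert out.frame["stabilized"].nunique() == 1
        assert out.frame["stabilized"].iloc[0] == pytest.approx(
            np.median(ws.frame["stabilized"])
        )

    def test_truncation_matches_sort_based_quantile_clipping(self):
        rng = np.random.default_rng(6)
        w = rng.lognormal(0, 0.8, size=200)
        frame = pd.DataFrame(
            {"subject_id": "x", "k": np.arange(200), "stabilized": w,
             "unstabilized": w}
        )
        ws = truncate_weights(WeightSeries(frame=frame), 5, 95)
        lo, hi = np.percentile(w, [5, 95])
        np.testing.assert_allclose(
            ws.frame["stabilized"], np.clip(w, lo, hi)
        )

    def test_truncation_narrowing_never_increases_sd(self, fitted_switch):
        _, _, ws = fitted_switch
        windows = [(0, 100), (1, 99), (5, 95), (10, 90), (25, 75), (50, 50)]
        sds = [
            weight_diagnostics(truncate_weights(ws, lo, hi)).sd
            for lo, hi in windows
        ]
        assert all(s1 >= s2 - 1e-12 for s1, s2 in zip(sds, sds[1:]))


class TestDiagnostics:
    def test_unit_weights_clean_diagnostics(self):
        frame = pd.DataFrame(
            {"subject_id": "a", "k": range(5), "stabilized": 1.0, "unstabilized": 1.0}
        )
        d = weight_diagnostics(WeightSeries(frame=frame))
        assert (d.mean, d.sd) == (1.0, 0.0)
        assert not d.flags

    def test_simple_moments(self):
        frame = pd.DataFrame(
            {
                "subject_id": "a",
                "k": range(3),
                "stabilized": [0.5, 1.0, 1.5],
                "unstabilized": 1.0,
            }
        )
        d = weight_diagnostics(WeightSeries(frame=frame))
        assert d.mean == pytest.approx(1.0)
        assert (d.min, d.max) == (0.5, 1.5)

    def test_wellspecified_stabilized_mean_near_one(self, fitted_switch):
        _, _, ws = fitted_switch
        d = weight_diagnostics(ws)
        assert 0.9 <= d.mean <= 1.1


@pytest.fixture(scope="module")
def screen_table():
    rng = np.random.default_rng(15)
    n = 2500
    strong = rng.normal(size=n)
    noise = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-2.0 + 0.9 * strong)))
    return pd.DataFrame(
        {
            "event": rng.uniform(size=n) < p,
            "strong": strong,
            "noise": noise,
            "flat": 1.0,
        }
    ).astype({"event": int})


class TestScreening:
    def test_strong_predictor_retained_null_excluded(self, screen_table):
        selected, report = screen_covariates(
            screen_table,
            [TermSpec("strong"), TermSpec("noise"), TermSpec("flat")],
            "event",
        )
        names = [t.name for t in selected]
        assert "strong" in names
        assert "flat" not in names
        flat_row = report.loc[report["term"] == "flat"].iloc[0]
        assert "constant" in flat_row["note"]

    def test_large_or_retained_regardless_of_p(self):
        # a two-row fake report path: OR 1.5 must be kept by the OR rule
        rng = np.random.default_rng(8)
        n = 60
        x = rng.integers(0, 2, n)
        p = np.where(x == 1, 0.35, 0.25)
        df = pd.DataFrame({"event": rng.uniform(size=n) < p, "x": x}).astype(
            {"event": int}
        )
        selected, report = screen_covariates(df, [TermSpec("x")], "event")
        row = report.iloc[0]
        if row["or"] < 0.75 or row["or"] > 1.33:
            assert row["selected"]

    def test_strong_effect_power(self):
        """A genuinely prognostic covariate at n = 500 person-intervals is
        retained in nearly every simulation repeat."""
        rng = np.random.default_rng(44)
        kept = 0
        n_rep = 40
        for _ in range(n_rep):
            x = rng.normal(size=500)
            p = 1 / (1 + np.exp(-(-1.5 + 1.0 * x)))
            df = pd.DataFrame(
                {"event": (rng.uniform(size=500) < p).astype(int), "x": x}
            )
            selected, _ = screen_covariates(df, [TermSpec("x")], "event")
            kept += bool(selected)
        assert kept >= int(0.95 * n_rep)


class TestSpecLadderBehaviour:
    def test_dropping_tdp_inflates_weight_sd(self, medium_cohort_table):
        """Removing time-since-progression from the switching model leaves
        systematic structure unexplained and destabilizes the weights."""
        full = compute_weights(
            fit_weight_models(medium_cohort_table, switching_spec_full()),
            medium_cohort_table,
        )
        dropped = compute_weights(
            fit_weight_models(medium_cohort_table, switching_spec_dropped_tdp()),
            medium_cohort_table,
        )
        d_full = weight_diagnostics(full)
        d_drop = weight_diagnostics(dropped)
        assert d_drop.sd > d_full.sd
        assert d_drop.max > d_full.max

    def test_random_switching_weights_recover_never_switch_truth(self):
        """Switching at a constant post-progression hazard is independent of
        every measured covariate, yet still informative: it censors only
        progressed (high-risk) person-time, so the raw censor-at-switch curve
        under-estimates the never-switch risk while the IPC-weighted curve
        recovers it."""
        from dataclasses import replace

        from gswitch.discrete_survival import km_curve
        from gswitch.synthetic_trial import simulate_truth

        cfg = replace(
            default_config(n_control=2500, n_experimental=0, seed=21),
            switching=SwitchingHazard(
                intercept=float(logit(0.08)), tls=0, ecog=0, tdp=0, age=0
            ),
        )
        table = generate_person_time(cfg)
        truth = simulate_truth(cfg, "always_control", 20_000)
        models = fit_weight_models(table, switching_spec_full())
        ws = compute_weights(models, table)
        ret = table.loc[(table["switched"] == 0) & (table["arm"] == 0)]
        w = ws.aligned_to(ret, "unstabilized")
        km_w = km_curve(ret, weights=w, horizon=48)
        km_u = km_curve(ret, horizon=48)
        se = np.sqrt(km_u.greenwood_se(48) ** 2 + truth.mc_se(48) ** 2)
        assert abs(km_w.risk_at(48) - truth.risk_at(48)) < 4 * se
        assert abs(km_u.risk_at(48) - truth.risk_at(48)) > 4 * se
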