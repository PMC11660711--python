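"""Person-time expansion, validation and design-matrix construction."""

import numpy as np
import pandas as pd
import pytest

from gswitch.core_data import (
    DesignBuilder,
    StructuralValidationError,
    SubjectRecord,
    TermSpec,
    build_design_matrix,
    collapse_person_time,
    expand_to_person_time,
    natural_spline_basis,
    read_person_time,
    validate_person_time,
    write_person_time,
)

from conftest import make_baseline, make_subject


class TestExpansion:
    def test_death_in_interval_three_gives_four_rows(self):
        t = expand_to_person_time([make_subject(death_month=3)], 48)
        assert list(t["k"]) == [0, 1, 2, 3]
        assert list(t["outcome"]) == [0, 0, 0, 1]
        assert t["censored"].sum() == 0

    def test_censoring_at_month_two(self):
        t = expand_to_person_time([make_subject(censor_month=2)], 48)
        assert list(t["k"]) == [0, 1, 2]
        assert list(t["censored"]) == [0, 0, 1]
        assert t["outcome"].sum() == 0

    def test_control_switcher_treatment_and_progression_columns(self):
        t = expand_to_person_time(
            [make_subject(progression_month=5, switch_month=8, death_month=12)], 48
        )
        assert (t.loc[t["k"] < 8, "treatment"] == 0).all()
        assert (t.loc[t["k"] >= 8, "treatment"] == 1).all()
        assert (t.loc[t["k"] < 5, "dp"] == 0).all()
        assert (t.loc[t["k"] >= 5, "dp"] == 1).all()
        # tdp counts months since onset, 0 before progression
        assert t.loc[t["k"] == 7, "tdp"].iloc[0] == 2
        assert (t.loc[t["k"] < 5, "tdp"] == 0).all()

    def test_event_free_subject_runs_to_horizon(self):
        t = expand_to_person_time([make_subject(max_followup_months=30)], 48)
        assert len(t) == 30
        t2 = expand_to_person_time([make_subject(max_followup_months=60)], 48)
        assert len(t2) == 48  # horizon truncation, complete intervals only

    def test_total_person_months_matches_per_subject_count(self):
        subjects = [
            make_subject("a", death_month=3),
            make_subject("b", censor_month=7),
            make_subject("c", max_followup_months=48),
        ]
        t = expand_to_person_time(subjects, 48)
        assert len(t) == (3 + 1) + (7 + 1) + 48

    def test_roundtrip_recovers_event_months(self, small_cohort_table):
        records = collapse_person_time(small_cohort_table)
        t2 = expand_to_person_time(records, 48)
        pd.testing.assert_frame_equal(
            small_cohort_table.reset_index(drop=True), t2.reset_index(drop=True)
        )

    def test_switch_without_progression_rejected(self):
        with pytest.raises(StructuralValidationError):
            make_subject(switch_month=3)

    def test_switch_on_experimental_arm_rejected(self):
        with pytest.raises(StructuralValidationError):
            make_subject(arm=1, progression_month=1, switch_month=3)

    def test_death_and_censoring_both_present_rejected(self):
        with pytest.raises(StructuralValidationError):
            make_subject(death_month=3, censor_month=3)


class TestValidation:
    def test_generated_table_is_valid(self, small_cohort_table):
        assert validate_person_time(small_cohort_table).ok

    def test_non_absorbing_progression_reported(self):
        t = expand_to_person_time([make_subject(progression_month=1, death_month=2)], 48)
        t.loc[t["k"] == 2, "dp"] = 0
        report = validate_person_time(t)
        assert any("non-absorbing dp" in v["rule"] for v in report.violations)

    def test_rows_after_death_reported(self):
        t = expand_to_person_time([make_subject(progression_month=0, death_month=2)], 48)
        t.loc[t["k"] == 1, "outcome"] = 1
        report = validate_person_time(t)
        assert any("rows after death" in v["rule"] for v in report.violations)

    def test_death_without_progression_reported(self):
        t = expand_to_person_time([make_subject(progression_month=1, death_month=3)], 48)
        t["dp"] = 0
        report = validate_person_time(t)
        assert any("gating" in v["rule"] for v in report.violations)


def _brute_force_natural_spline(x, knots):
    """Textbook truncated-power natural cubic spline basis, scalar loops."""
    K = len(knots)
    out = []
    for xi in x:
        def d(j):
            a = max(xi - knots[j], 0.0) ** 3 - max(xi - knots[K - 1], 0.0) ** 3
            return a / (knots[K - 1] - knots[j])
        row = [xi] + [d(j) - d(K - 2) for j in range(K - 2)]
        out.append(row)
    return np.array(out)


class TestDesignMatrix:
    def test_linear_term_is_identity(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        X, labels, _ = build_design_matrix(df, [TermSpec("x")], add_intercept=False)
        assert labels == ["x"]
        np.testing.assert_array_equal(X[:, 0], [1, 2, 3])

    def test_quadratic_term(self):
        df = pd.DataFrame({"x": [4.0]})
        X, labels, _ = build_design_matrix(
            df, [TermSpec("x", transform="quadratic")], add_intercept=False
        )
        np.testing.assert_array_equal(X[0], [4.0, 16.0])
        assert labels == ["x", "x^2"]

    def test_categorical_indicators_against_lowest_code(self):
        df = pd.DataFrame({"c": [0, 1, 2, 1]})
        X, labels, _ = build_design_matrix(
            df, [TermSpec("c", transform="categorical", n_levels=3)],
            add_intercept=False,
        )
        assert labels == ["c[1]", "c[2]"]
        np.testing.assert_array_equal(X, [[0, 0], [1, 0], [0, 1], [1, 0]])

    def test_spline_basis_matches_brute_force_at_knots(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, size=200)
        builder = DesignBuilder([TermSpec("x", transform="spline5")],
                                add_intercept=False)
        df = pd.DataFrame({"x": x})
        X, labels = builder.fit_transform(df)
        knots = builder.knots["x"]
        np.testing.assert_allclose(
            knots, np.percentile(x, [5, 27.5, 50, 72.5, 95])
        )
        expected = _brute_force_natural_spline(knots, knots)
        got = natural_spline_basis(np.array(knots), knots)
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        assert X.shape == (200, 4) and len(labels) == 4

    def test_spline_is_linear_beyond_boundary_knots(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 100)
        builder = DesignBuilder([TermSpec("x", transform="spline5")],
                                add_intercept=False)
        builder.fit(pd.DataFrame({"x": x}))
        right = np.array([2.0, 3.0, 4.0])
        B, _ = builder.transform(pd.DataFrame({"x": right}))
        # second differences of each basis column vanish on a linear segment
        second_diff = B[2] - 2 * B[1] + B[0]
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-9)

    def test_unseen_category_at_transform_raises(self):
        builder = DesignBuilder([TermSpec("c", transform="categorical", n_levels=4)])
        builder.fit(pd.DataFrame({"c": [0, 1, 2]}))
        with pytest.raises(StructuralValidationError, match="unseen"):
            builder.transform(pd.DataFrame({"c": [3]}))

    def test_constant_spline_column_raises(self):
        with pytest.raises(StructuralValidationError, match="degenerate"):
            DesignBuilder([TermSpec("x", transform="spline5")]).fit(
                pd.DataFrame({"x": [1.0] * 50})
            )

    def test_design_matrix_deterministic(self, small_cohort_table):
        terms = [
            TermSpec("tls", transform="spline5"),
            TermSpec("strata", "baseline", "categorical", 4),
            TermSpec("k", transform="quadratic"),
        ]
        X1, l1, _ = build_design_matrix(small_cohort_table, terms)
        X2, l2, _ = build_design_matrix(small_cohort_table, terms)
        assert l1 == l2
        np.testing.assert_array_equal(X1, X2)


def test_person_time_csv_roundtrip(tmp_path, small_cohort_table):
    path = tmp_path / "pt.csv"
    write_person_time(small_cohort_table, path)
    back = read_person_time(path)
    pd.testing.assert_frame_equal(
        small_cohort_table.reset_index(drop=True), back, check_dtype=False
    )
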