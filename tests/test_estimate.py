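"""Logistic-estimation checks against closed forms and simulation oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from cohortsens.cohort import CohortTable, Role, Variable, VarType
from cohortsens.estimate import (FitError, InsufficientDataError,
                                 ExposureOutcomeModel, compare_cohorts,
                                 run_scenarios)
from cohortsens.synthdata import default_spec, generate

from conftest import two_by_two_table


class TestSaturated2x2:
    def test_matches_closed_form_log_or_and_se(self, table_50_50_25_75):
        res = ExposureOutcomeModel(table_50_50_25_75, "unadjusted").fit()
        assert res.log_or == pytest.approx(math.log(3.0), abs=1e-6)
        assert res.se == pytest.approx(
            math.sqrt(1 / 50 + 1 / 50 + 1 / 25 + 1 / 75), abs=1e-6)
        assert res.ci[0] <= res.odds_ratio <= res.ci[1]
        assert res.n_used == 200

    def test_null_table_gives_zero_log_or(self):
        res = ExposureOutcomeModel(two_by_two_table(30, 70, 30, 70), "unadjusted").fit()
        assert res.log_or == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0, abs=1e-6)


def test_complete_case_count_excludes_rows_missing_model_variables():
    df = pd.DataFrame({
        "x": [0, 1, 0, 1, np.nan, 0, 1, 0],
        "c": [1.0, 2.0, np.nan, 0.5, 1.0, 0.2, 0.9, 1.1],
        "y": [0, 1, 1, 0, 1, np.nan, 1, 0],
    })
    table = CohortTable.from_dataframe(
        df, {"x": Role.EXPOSURE, "c": Role.CONFOUNDER, "y": Role.OUTCOME},
        types={"x": VarType.BINARY, "y": VarType.BINARY})
    model = ExposureOutcomeModel(table, "confounders_only")
    assert len(model._y) == 5


def test_large_n_adjusted_fit_recovers_truth():
    spec = default_spec(n=100_000, u_coef_exposure=0.0, u_coef_outcome=0.0,
                        mediator_confounding=0.0)
    table, truth = generate(spec, 3)
    res = ExposureOutcomeModel(table, "confounders_only").fit()
    assert res.log_or == pytest.approx(truth.beta_xy_true, abs=0.04)


def test_separation_error_names_a_variable():
    df = pd.DataFrame({
        "x": [0, 0, 1, 1] * 10,
        "s": [0, 0, 1, 1] * 10,      # s == y: perfect separation
        "y": [0, 0, 1, 1] * 10,
    })
    table = CohortTable.from_dataframe(
        df, {"x": Role.EXPOSURE, "s": Role.CONFOUNDER, "y": Role.OUTCOME})
    with pytest.raises(FitError) as err:
        ExposureOutcomeModel(table, "confounders_only").fit()
    assert err.value.variable is not None


def test_insufficient_rows_raise():
    table = two_by_two_table(1, 0, 1, 0)
    with pytest.raises(InsufficientDataError):
        ExposureOutcomeModel(table, "unadjusted").fit()


class TestRiskDifference:
    def test_zero_exposure_coefficient_gives_zero_pp(self):
        res = ExposureOutcomeModel(two_by_two_table(30, 70, 30, 70), "unadjusted").fit()
        rd = res.risk_difference(n_boot=50, seed=1)
        assert rd.rd_pp == pytest.approx(0.0, abs=1e-6)

    def test_no_covariates_collapses_to_raw_proportion_difference(self, table_50_50_25_75):
        res = ExposureOutcomeModel(table_50_50_25_75, "unadjusted").fit()
        rd = res.risk_difference(n_boot=200, seed=2)
        assert rd.rd_pp == pytest.approx(25.0, abs=1e-6)
        assert rd.ci[0] <= rd.rd_pp <= rd.ci[1]


class TestCompareCohorts:
    def test_identical_estimates_give_z_zero(self, table_50_50_25_75):
        res = ExposureOutcomeModel(table_50_50_25_75, "unadjusted").fit()
        z, p = compare_cohorts(res, res)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_z(self):
        a = _fake_estimate(0.405, 0.074)
        b = _fake_estimate(0.143, 0.075)
        z, p = compare_cohorts(a, b)
        assert z == pytest.approx(2.487, abs=0.005)
        assert p == pytest.approx(0.013, abs=0.001)
        z2, p2 = compare_cohorts(b, a)
        assert z2 == -z and p2 == p


def _fake_estimate(log_or, se):
    from cohortsens.estimate import EffectResults
    return EffectResults(log_or=log_or, se=se, ci=(0, 0), p=0, n_used=0,
                         scenario="custom", ci_level=0.95, exposure="x", outcome="y")


class TestScenarioRunner:
    def test_without_mediator_roles_the_two_adjusted_fits_coincide(self):
        spec = default_spec(n=3000)
        table, _ = generate(spec, 5)
        # re-declare the time-3 variable as a plain confounder-free column
        new_vars = [Variable(v.name, v.vtype,
                             Role.OTHER if v.role == Role.CONFOUNDER_OR_MEDIATOR else v.role)
                    for v in table.variables]
        table2 = CohortTable(table.data.copy(), new_vars)
        bracket = run_scenarios(table2)
        e1 = bracket.estimates["confounders_only"]
        e2 = bracket.estimates["confounders_and_mediators"]
        assert e1.log_or == pytest.approx(e2.log_or, abs=1e-12)
        assert bracket.bracket[0] == pytest.approx(bracket.bracket[1])

    def test_adjusting_for_pure_mediator_attenuates_and_brackets_truth(self):
        # strong pure mediator of a true effect: the over-controlled fit is
        # strictly attenuated and the bracket straddles the mediated share
        spec = default_spec(n=100_000, u_coef_exposure=0.0, u_coef_outcome=0.0,
                            mediator_confounding=0.0)
        spec.mediator_t3_model.coefs["attend"] = 1.2
        spec.outcome_model.coefs["married_t3"] = 0.8
        table, truth = generate(spec, 11)
        bracket = run_scenarios(table)
        conf_only = bracket.estimates["confounders_only"].log_or
        with_med = bracket.estimates["confounders_and_mediators"].log_or
        assert with_med < conf_only
        assert bracket.bracket[0] <= truth.beta_xy_true + 0.05
        assert bracket.sign_agreement is True


def test_independent_noise_covariate_barely_moves_the_estimate():
    spec = default_spec(n=30_000)
    table, _ = generate(spec, 19)
    base = ExposureOutcomeModel(table, "confounders_only").fit()
    rng = np.random.default_rng(0)
    df = table.data.copy()
    df["noise"] = rng.standard_normal(len(df))
    vars2 = list(table.variables)
    vars2.insert(0, Variable("noise", VarType.CONTINUOUS, Role.CONFOUNDER))
    table2 = CohortTable(df, vars2)
    res2 = ExposureOutcomeModel(table2, "confounders_only").fit()
    assert abs(res2.log_or - base.log_or) < 2 * base.se


def test_wald_ci_coverage_near_nominal():
    # 500 simulated cohorts at n=2000: the 95% CI covers the planted effect
    # in 95% +/- 3% of runs
    spec = default_spec(n=2000, u_coef_exposure=0.0, u_coef_outcome=0.0,
                        mediator_confounding=0.0)
    covered = 0
    for rep in range(500):
        table, truth = generate(spec, 1000 + rep)
        res = ExposureOutcomeModel(table, "confounders_only").fit()
        lo, hi = res.ci_log
        covered += lo <= truth.beta_xy_true <= hi
    assert covered / 500 == pytest.approx(0.95, abs=0.03)
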