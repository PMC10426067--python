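"""Generalised sensitivity analysis: benchmarks, calibration, frontier."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cohortsens.cohort import CohortTable, Role, Variable, VarType
from cohortsens.estimate import ExposureOutcomeModel, build_design
from cohortsens.gsa import GsaAnalysis, GsaConfig
from cohortsens.synthdata import default_spec, generate


def _oracle_partials(table, covariates, v):
    """Independent residual-on-residual partial correlations."""
    y, X = build_design(table, covariates)
    yv = y.to_numpy()
    x = X[table.exposure].to_numpy()
    Z = X[[c for c in X.columns if c != table.exposure]].to_numpy()
    Zx = np.column_stack([Z, x])
    ex = x - sm.Logit(x, Z).fit(disp=0).predict(Z)
    ey = yv - sm.Logit(yv, Zx).fit(disp=0).predict(Zx)
    rv_z = v - Z @ np.linalg.lstsq(Z, v, rcond=None)[0]
    rv_zx = v - Zx @ np.linalg.lstsq(Zx, v, rcond=None)[0]
    r_x = np.corrcoef(rv_z, ex)[0, 1]
    r_y = np.corrcoef(rv_zx, ey)[0, 1]
    return r_x, r_y


@pytest.fixture(scope="module")
def planted_table():
    """Null true effect with one strong unmeasured confounder exposed."""
    spec = default_spec(n=20_000, beta_xy=0.0, u_coef_exposure=0.8,
                        u_coef_outcome=0.8, expose_u=True)
    table, truth = generate(spec, 7)
    return table, truth


class TestBenchmarks:
    def test_pure_noise_covariate_benchmarks_near_zero(self):
        spec = default_spec(n=50_000)
        table, _ = generate(spec, 31)
        rng = np.random.default_rng(5)
        df = table.data.copy()
        df["noise"] = rng.standard_normal(len(df))
        vars2 = list(table.variables) + [Variable("noise", VarType.CONTINUOUS, Role.CONFOUNDER)]
        table2 = CohortTable(df, vars2)
        bm = {b.name: b for b in GsaAnalysis(table2, "confounders_only").benchmarks()}
        assert abs(bm["noise"].r_x) < 0.02 and abs(bm["noise"].r_y) < 0.02

    def test_matches_brute_force_partial_correlations(self, planted_table):
        table, _ = planted_table
        ga = GsaAnalysis(table, "confounders_only")
        bm = {b.name: b for b in ga.benchmarks(extra=["u"])}
        # extra variable: conditioning on the full adjustment set
        covs = table.confounders
        v = table.data["u"].to_numpy()
        r_x, r_y = _oracle_partials(table, covs, v)
        assert bm["u"].r_x == pytest.approx(r_x, abs=1e-10)
        assert bm["u"].r_y == pytest.approx(r_y, abs=1e-10)
        # leave-one-out benchmark of an observed covariate
        y, X = build_design(table, covs)
        v_age = X["age"].to_numpy()
        r_x2, r_y2 = _oracle_partials(table, [c for c in covs if c != "age"], v_age)
        assert bm["age"].r_x == pytest.approx(r_x2, abs=1e-10)
        assert bm["age"].r_y == pytest.approx(r_y2, abs=1e-10)

    def test_duplicated_covariate_reproduces_original_benchmark(self):
        spec = default_spec(n=8000)
        table, _ = generate(spec, 3)
        base = {b.name: b for b in GsaAnalysis(table, "confounders_only").benchmarks()}
        df = table.data.copy()
        df["age2"] = df["age"]
        vars2 = [Variable("age", VarType.CONTINUOUS, Role.OTHER) if v.name == "age" else v
                 for v in table.variables]
        vars2.append(Variable("age2", VarType.CONTINUOUS, Role.CONFOUNDER))
        dup = {b.name: b for b in GsaAnalysis(CohortTable(df, vars2), "confounders_only").benchmarks()}
        assert dup["age2"].r_x == pytest.approx(base["age"].r_x, abs=1e-10)
        assert dup["age2"].r_y == pytest.approx(base["age"].r_y, abs=1e-10)


class TestCalibration:
    def test_zero_targets_leave_estimate_unchanged(self, planted_table):
        table, _ = planted_table
        ga = GsaAnalysis(table, "confounders_only")
        cal = ga.calibrate(0.0, 0.0, seed=4)
        assert cal.converged
        base = ExposureOutcomeModel(table, "confounders_only").fit()
        df = table.data.copy()
        df["u_pseudo"] = cal.u
        vars2 = list(table.variables) + [Variable("u_pseudo", VarType.CONTINUOUS, Role.CONFOUNDER)]
        res = ExposureOutcomeModel(CohortTable(df, vars2), "confounders_only").fit()
        assert abs(res.log_or - base.log_or) < 2 * base.se

    def test_moderate_targets_achieved_within_tolerance(self, planted_table):
        table, _ = planted_table
        ga = GsaAnalysis(table, "confounders_only", GsaConfig(tol=0.01))
        cal = ga.calibrate(0.2, 0.2, seed=8)
        assert cal.converged
        # independent recomputation of the achieved partial correlations
        r_x, r_y = _oracle_partials(table, table.confounders, cal.u)
        assert r_x == pytest.approx(0.2, abs=0.01)
        assert r_y == pytest.approx(0.2, abs=0.01)

    def test_binary_u_extreme_target_flagged_nonconvergent(self, planted_table):
        table, _ = planted_table
        ga = GsaAnalysis(table, "confounders_only",
                         GsaConfig(u_type="binary", max_iter=60))
        cal = ga.calibrate(0.9, 0.9, seed=9)
        assert not cal.converged
        assert set(np.unique(cal.u)) <= {0.0, 1.0}

    def test_binary_u_moderate_targets_achieved(self, planted_table):
        table, _ = planted_table
        ga = GsaAnalysis(table, "confounders_only", GsaConfig(u_type="binary", tol=0.01))
        cal = ga.calibrate(0.15, 0.15, seed=10)
        assert cal.converged
        assert cal.achieved_r_x == pytest.approx(0.15, abs=0.02)


class TestFrontier:
    def test_null_unconfounded_estimate_gives_degenerate_frontier(self):
        spec = default_spec(n=20_000, beta_xy=0.0,
                            u_coef_exposure=0.0, u_coef_outcome=0.0)
        table, _ = generate(spec, 23)
        fr = GsaAnalysis(table, "confounders_only",
                         GsaConfig(grid=(0.1,), k_draws=5)).frontier()
        assert fr.notice is not None
        assert fr.points[0].r_x == 0.0 and fr.points[0].r_y == 0.0

    def test_significance_frontier_below_point_frontier(self, planted_table):
        table, _ = planted_table
        base = dict(grid=(0.25,), k_draws=10, seed=2)
        fr_point = GsaAnalysis(table, "confounders_only",
                               GsaConfig(target="nullify_point", **base)).frontier()
        fr_sig = GsaAnalysis(table, "confounders_only",
                             GsaConfig(target="nullify_significance", **base)).frontier()
        assert fr_sig.points[0].r_y < fr_point.points[0].r_y

    def test_same_seed_reproduces_frontier(self, planted_table):
        table, _ = planted_table
        cfg = GsaConfig(grid=(0.2,), k_draws=5, seed=77)
        f1 = GsaAnalysis(table, "confounders_only", cfg).frontier()
        f2 = GsaAnalysis(table, "confounders_only", cfg).frontier()
        assert f1.points[0].r_y == pytest.approx(f2.points[0].r_y, abs=1e-4)

    def test_frontier_monotone_after_monotonization(self, planted_table):
        table, _ = planted_table
        cfg = GsaConfig(grid=(0.1, 0.2, 0.3), k_draws=5, seed=5)
        fr = GsaAnalysis(table, "confounders_only", cfg).frontier()
        rys = [p.r_y for p in fr.points if not math.isnan(p.r_y)]
        assert all(a >= b for a, b in zip(rys, rys[1:]))
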