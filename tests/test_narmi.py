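"""Delta-adjusted (Not-At-Random) imputation and tipping-point detection."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from cohortsens.cohort import CohortTable, Role, Variable, VarType
from cohortsens.mi_engine import ImputationSet, MiConfig, PooledEstimate, impute
from cohortsens.narmi import (DeltaGridSpec, TippingCell, csp_to_msp,
                              find_tipping, impute_delta, tipping_grid)
from cohortsens.synthdata import (LinearPredictor, MissingnessModel,
                                  default_spec, generate, impose_missingness)


@pytest.fixture(scope="module")
def mnar_cohort():
    spec = default_spec(preset="partners", n=2000, u_coef_exposure=0.0,
                        u_coef_outcome=0.0, mnar_delta_exposure=-1.0,
                        mnar_delta_outcome=-1.0)
    table, truth = generate(spec, 41)
    return impose_missingness(table, spec, 41, truth), truth


class TestDeltaGridSpec:
    def test_requires_zero_anchor(self):
        with pytest.raises(ValueError):
            DeltaGridSpec(deltas=(-0.5, -1.0))

    def test_cell_counts_by_mode(self):
        deltas = (0.0, -0.5, -1.0)
        assert len(DeltaGridSpec(deltas, "exposure_only").cells()) == 3
        assert len(DeltaGridSpec(deltas, "outcome_only").cells()) == 3
        assert len(DeltaGridSpec(deltas, "both").cells()) == 9

    def test_default_grid_spans_zero_to_minus_two(self):
        g = DeltaGridSpec()
        assert g.deltas[0] == 0.0
        assert g.deltas[-1] == pytest.approx(-2.0)
        assert len(g.deltas) == 9


def test_delta_zero_is_bitwise_equal_to_standard_mi(mnar_cohort):
    observed, _ = mnar_cohort
    cfg = MiConfig(m=3, burnin=3, seed=9)
    std = impute(observed, cfg)
    nar = impute_delta(observed, cfg, {"attend": 0.0, "donate": 0.0})
    for a, b in zip(std.tables, nar.tables):
        pd.testing.assert_frame_equal(a, b)


def test_delta_on_non_binary_variable_rejected(mnar_cohort):
    observed, _ = mnar_cohort
    with pytest.raises(ValueError, match="age"):
        impute_delta(observed, MiConfig(m=2, burnin=1, seed=0), {"age": -1.0})


def test_intercept_only_delta_shift_matches_closed_form():
    # single incomplete binary variable, no predictors: imputed probability
    # must be expit(logit(p_obs) + delta)
    rng = np.random.default_rng(3)
    n = 4000
    x = rng.binomial(1, 0.5, n).astype(float)
    y = rng.binomial(1, 0.4, n).astype(float)
    y[rng.random(n) < 0.5] = np.nan
    table = CohortTable(pd.DataFrame({"x": x, "y": y}),
                        [Variable("x", VarType.BINARY, Role.EXPOSURE),
                         Variable("y", VarType.BINARY, Role.OUTCOME)])
    pm = pd.DataFrame(False, index=["x", "y"], columns=["x", "y"])
    cfg = MiConfig(m=20, burnin=2, seed=5, predictor_matrix=pm)
    delta = -2.0
    imps = impute_delta(table, cfg, {"y": delta})
    p_obs = np.nanmean(y)
    expected = expit(logit(p_obs) + delta)
    mask = imps.mask["y"].to_numpy()
    imputed_mean = np.mean([t.loc[mask, "y"].mean() for t in imps.tables])
    n_mis = int(mask.sum())
    se = math.sqrt(expected * (1 - expected) / (n_mis * len(imps.tables)))
    assert abs(imputed_mean - expected) < 3 * se + 0.01


def test_imputed_prevalence_monotone_in_delta(mnar_cohort):
    observed, _ = mnar_cohort
    means = []
    for d in (0.0, -0.5, -1.0, -1.5, -2.0):
        imps = impute_delta(observed, MiConfig(m=4, burnin=3, seed=7),
                            {"attend": d, "donate": 0.0})
        mask = imps.mask["attend"].to_numpy()
        means.append(np.mean([t.loc[mask, "attend"].mean() for t in imps.tables]))
    assert all(a >= b - 0.01 for a, b in zip(means, means[1:]))
    assert means[0] > means[-1]


class TestCspToMsp:
    def _toy_imps(self, imputed_positive: int):
        # observed: 30/100 positive; 50 originally-missing cells imputed at
        # a fixed number positive
        obs = np.array([1.0] * 30 + [0.0] * 70 + [np.nan] * 50)
        x = np.zeros(150)
        df = pd.DataFrame({"x": x, "y": obs})
        variables = [Variable("x", VarType.BINARY, Role.EXPOSURE),
                     Variable("y", VarType.BINARY, Role.OUTCOME)]
        filled = df.copy()
        filled.loc[filled["y"].isna(), "y"] = np.array(
            [1.0] * imputed_positive + [0.0] * (50 - imputed_positive))
        return ImputationSet(tables=[filled, filled.copy()], mask=df.isna(),
                             variables=variables, chain_means={},
                             config=MiConfig(m=2, burnin=1))

    def test_fixed_prevalence_matches_direct_arithmetic(self):
        imps = self._toy_imps(10)    # 20% positive among missing
        msp, prev, flagged = csp_to_msp(imps, "y")
        assert msp == pytest.approx(logit(0.2) - logit(0.3), abs=1e-12)
        assert prev == pytest.approx(0.2)
        assert not flagged

    def test_empty_cell_applies_continuity_correction_and_flags(self):
        imps = self._toy_imps(0)
        msp, prev, flagged = csp_to_msp(imps, "y")
        assert flagged and prev == 0.0 and math.isfinite(msp)


def test_mar_missingness_implies_small_msp():
    spec = default_spec(n=10_000)   # auxiliary-driven MAR missingness
    table, truth = generate(spec, 51)
    observed = impose_missingness(table, spec, 51, truth)
    imps = impute(observed, MiConfig(m=5, burnin=4, seed=2))
    msp, _, _ = csp_to_msp(imps, "attend")
    # MAR given auxiliaries leaves only the auxiliary-explained gap
    assert abs(msp) < 0.35


class TestTippingGrid:
    def test_anchor_cell_reproduces_standard_mi(self, mnar_cohort):
        observed, _ = mnar_cohort
        cfg = MiConfig(m=3, burnin=2, seed=17)
        cells = tipping_grid(observed, cfg, DeltaGridSpec((0.0, -1.0), "exposure_only"))
        anchor = next(c for c in cells if c.csp_exposure == 0.0)
        from cohortsens.mi_engine import pool_logistic
        std = pool_logistic(impute(observed, cfg), "confounders_only")
        assert anchor.pooled.qbar == pytest.approx(std.qbar, abs=1e-12)
        assert len(cells) == 2
        assert all(c.msp_exposure is not None for c in cells if c.ok)

    def test_matched_delta_recovers_prevalence_among_missing(self, mnar_cohort):
        # the quantity delta adjustment provably fixes: the prevalence of the
        # positive level among originally-missing records
        observed, truth = mnar_cohort
        mask = observed.data["attend"].isna().to_numpy()
        true_prev = truth.complete_table.data["attend"].to_numpy()[mask].mean()
        errs = {}
        for d in (0.0, -1.0):
            imps = impute_delta(observed, MiConfig(m=6, burnin=4, seed=19),
                                {"attend": d, "donate": d})
            _, prev, _ = csp_to_msp(imps, "attend")
            errs[d] = abs(prev - true_prev)
        assert errs[-1.0] < errs[0.0]


class TestFindTipping:
    def _cell(self, dx, dy, qbar, lo, hi):
        pe = PooledEstimate(qbar=qbar, w=0.01, b=0.001, t=0.0115, df=50.0,
                            m=5, ci=(lo, hi), p=0.05)
        return TippingCell(csp_exposure=dx, csp_outcome=dy, pooled=pe)

    def test_no_flip_reports_no_tipping_point(self):
        cells = [self._cell(d, d, 0.4, 1.2, 1.8) for d in (0.0, -0.5, -1.0)]
        rep = find_tipping(cells)
        assert not rep.tipped
        assert "no tipping point" in rep.summary()

    def test_flip_between_grid_cells_reports_first_past_the_flip(self):
        cells = [self._cell(0.0, 0.0, 0.4, 1.2, 1.8),
                 self._cell(-0.5, -0.5, 0.3, 1.1, 1.7),
                 self._cell(-0.75, -0.75, 0.25, 1.05, 1.6),
                 self._cell(-1.0, -1.0, 0.2, 0.95, 1.5),
                 self._cell(-1.25, -1.25, 0.1, 0.90, 1.4)]
        rep = find_tipping(cells, "ci_includes_null")
        assert rep.tipped and rep.tipping_delta == (-1.0, -1.0)

    def test_already_flipped_anchor_reports_zero_delta(self):
        cells = [self._cell(0.0, 0.0, 0.05, 0.9, 1.3),
                 self._cell(-0.5, -0.5, 0.0, 0.85, 1.25)]
        rep = find_tipping(cells)
        assert rep.tipped and rep.tipping_delta == (0.0, 0.0)
        assert rep.notice is not None
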