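"""Complete-case logistic estimation of the exposure–outcome association.

Three nested adjustment scenarios are supported, reflecting uncertainty
about which covariates are confounders and which may also be mediators:

``unadjusted``
    exposure only;
``confounders_only``
    adds variables with role ``confounder`` (likely to under-control);
``confounders_and_mediators``
    additionally adjusts for ``confounder_or_mediator`` variables (likely
    to over-control by removing any mediated effect).

Run together, the two adjusted scenarios bracket the minimum and maximum
plausible causal estimates under correct confounder measurement.

The model object follows statsmodels conventions: build an
:class:`ExposureOutcomeModel` from a :class:`~cohortsens.cohort.CohortTable`
(or via :meth:`ExposureOutcomeModel.from_dataframe`), call :meth:`fit` to
obtain :class:`EffectResults` carrying the log odds ratio, Wald interval,
p-value and a ``summary()`` table; probability-scale effects come from
:meth:`EffectResults.risk_difference` (marginal standardization with a
seeded percentile bootstrap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning
import warnings

from .cohort import CohortTable, VarType

__all__ = [
    "SCENARIOS",
    "scenario_covariates",
    "FitError",
    "InsufficientDataError",
    "ExposureOutcomeModel",
    "EffectResults",
    "RiskDifference",
    "compare_cohorts",
    "run_scenarios",
    "ScenarioBracket",
]

UNADJUSTED = "unadjusted"
CONFOUNDERS_ONLY = "confounders_only"
CONFOUNDERS_AND_MEDIATORS = "confounders_and_mediators"
SCENARIOS = (UNADJUSTED, CONFOUNDERS_ONLY, CONFOUNDERS_AND_MEDIATORS)


class FitError(RuntimeError):
    """Logistic fit failed; carries the offending variable when known."""

    def __init__(self, message: str, variable: str | None = None):
        super().__init__(message)
        self.variable = variable


class InsufficientDataError(FitError):
    pass


def scenario_covariates(table: CohortTable, scenario: str) -> list[str]:
    """Resolve a scenario id to its adjustment set from the table's role map."""
    if scenario == UNADJUSTED:
        return []
    if scenario == CONFOUNDERS_ONLY:
        return table.confounders
    if scenario == CONFOUNDERS_AND_MEDIATORS:
        return table.confounders + table.confounders_or_mediators
    raise ValueError(f"unknown scenario {scenario!r}")


def _reference_level(col: pd.Series) -> object:
    counts = col.dropna().value_counts()
    return counts.index[0]  # most frequent; ties broken by count order


def build_design(
    table: CohortTable,
    covariates: list[str],
    reference_levels: Mapping[str, object] | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Listwise-deleted response and design matrix (with intercept).

    Categorical covariates expand to indicator contrasts against the most
    frequent level unless a reference level is configured.
    """
    cols = [table.exposure, *covariates, table.outcome]
    sub = table.data[cols].dropna()
    y = sub[table.outcome].astype(float)
    parts = {"const": pd.Series(1.0, index=sub.index), table.exposure: sub[table.exposure].astype(float)}
    for name in covariates:
        if table.var(name).vtype == VarType.CATEGORICAL:
            ref = (reference_levels or {}).get(name, _reference_level(sub[name]))
            for level in sorted(set(sub[name].unique()) - {ref}, key=str):
                parts[f"{name}[{level}]"] = (sub[name] == level).astype(float)
        else:
            parts[name] = sub[name].astype(float)
    X = pd.DataFrame(parts, index=sub.index)
    return y, X


def _find_separating_variable(y: np.ndarray, X: pd.DataFrame) -> str | None:
    for name in X.columns:
        if name == "const":
            continue
        x = X[name].to_numpy()
        lo, hi = y[x <= np.median(x)], y[x > np.median(x)]
        for side in (x == x.min(), x == x.max()):
            if side.any() and len(np.unique(y[side])) == 1 and side.sum() < len(y):
                if len(np.unique(y)) > 1:
                    return name
        del lo, hi
    return None


@dataclass
class RiskDifference:
    """Marginal-standardization risk difference, percentage points."""

    rd_pp: float
    ci: tuple[float, float]
    n_boot: int


@dataclass
class EffectResults:
    """Fitted exposure effect on the log-odds scale plus fit context."""

    log_or: float
    se: float
    ci: tuple[float, float]      # on the odds-ratio scale
    p: float
    n_used: int
    scenario: str
    ci_level: float
    exposure: str
    outcome: str
    model: "ExposureOutcomeModel" = field(repr=False, default=None)
    _smres: object = field(repr=False, default=None)
    rd_pp: RiskDifference | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_log(self) -> tuple[float, float]:
        return (math.log(self.ci[0]), math.log(self.ci[1]))

    def risk_difference(self, n_boot: int = 500, seed: int = 0) -> RiskDifference:
        """Percentage-point change in outcome probability under exposure.

        Marginal standardization: mean predicted probability over the
        complete-case rows with the exposure forced to 1 minus forced to 0,
        times 100. The CI is a seeded nonparametric percentile bootstrap of
        rows (model refitted per resample).
        """
        y, X = self.model._y, self.model._X
        point = _marginal_rd(np.asarray(self._smres.params), X, self.exposure)
        rng = np.random.default_rng(seed)
        n = len(y)
        draws = []
        yv, Xv = y.to_numpy(), X.to_numpy()
        cols = list(X.columns)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Xb = pd.DataFrame(Xv[idx], columns=cols)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(yv[idx], Xb).fit(disp=0, maxiter=100)
                draws.append(_marginal_rd(np.asarray(res.params), Xb, self.exposure))
            except (PerfectSeparationError, np.linalg.LinAlgError):
                continue
        alpha = 1.0 - self.ci_level
        lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
        rd = RiskDifference(rd_pp=point, ci=(float(lo), float(hi)), n_boot=n_boot)
        self.rd_pp = rd
        return rd

    def evalue(self, outcome_common: bool = True):
        """E-value analysis of this estimate (see :mod:`cohortsens.evalue`)."""
        from .evalue import evalue_analysis

        return evalue_analysis(self.odds_ratio, ci=self.ci, outcome_common=outcome_common)

    def summary(self) -> str:
        lines = [
            "Exposure-outcome logistic regression (complete case)",
            "=" * 56,
            f"exposure: {self.exposure}    outcome: {self.outcome}",
            f"scenario: {self.scenario}    n used: {self.n_used}",
            "-" * 56,
            f"log OR   {self.log_or: .4f}   (SE {self.se:.4f})",
            f"OR       {self.odds_ratio: .4f}   "
            f"{100 * self.ci_level:.0f}% CI ({self.ci[0]:.4f}, {self.ci[1]:.4f})",
            f"p-value  {self.p: .4g}",
        ]
        if self.rd_pp is not None:
            lines.append(
                f"risk difference {self.rd_pp.rd_pp: .2f} pp   "
                f"CI ({self.rd_pp.ci[0]:.2f}, {self.rd_pp.ci[1]:.2f})"
            )
        return "\n".join(lines)


def _marginal_rd(params: np.ndarray, X: pd.DataFrame, exposure: str) -> float:
    X1, X0 = X.copy(), X.copy()
    X1[exposure] = 1.0
    X0[exposure] = 0.0
    from scipy.special import expit

    p1 = expit(X1.to_numpy() @ params)
    p0 = expit(X0.to_numpy() @ params)
    return float((p1.mean() - p0.mean()) * 100.0)


class ExposureOutcomeModel:
    """Complete-case logistic model of a binary outcome on a binary exposure.

    Parameters
    ----------
    table
        Cohort with declared roles.
    scenario
        One of ``unadjusted``, ``confounders_only``,
        ``confounders_and_mediators``, or an explicit covariate list.
    ci_level
        Confidence level for Wald intervals (default 0.95).
    """

    def __init__(
        self,
        table: CohortTable,
        scenario: str | list[str] = CONFOUNDERS_ONLY,
        ci_level: float = 0.95,
        reference_levels: Mapping[str, object] | None = None,
    ):
        self.table = table
        if isinstance(scenario, str):
            self.scenario = scenario
            self.covariates = scenario_covariates(table, scenario)
        else:
            self.scenario = "custom"
            self.covariates = list(scenario)
        self.ci_level = ci_level
        self._y, self._X = build_design(table, self.covariates, reference_levels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, roles: Mapping[str, str], **kwargs):
        return cls(CohortTable.from_dataframe(df, roles), **kwargs)

    def fit(self) -> EffectResults:
        y, X = self._y, self._X
        n_used, k = X.shape
        if n_used < k + 1:
            raise InsufficientDataError(
                f"{n_used} complete-case rows for {k} parameters", variable=None
            )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                smres = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            var = _find_separating_variable(y.to_numpy(), X)
            raise FitError(f"complete separation (variable {var!r})", variable=var) from exc
        if not smres.mle_retvals.get("converged", True) or not np.isfinite(smres.bse).all():
            var = _find_separating_variable(y.to_numpy(), X)
            raise FitError(f"fit did not converge (suspect {var!r})", variable=var)
        exp_name = self.table.exposure
        log_or = float(smres.params[exp_name])
        se = float(smres.bse[exp_name])
        z = stats.norm.ppf(0.5 + self.ci_level / 2)
        ci = (math.exp(log_or - z * se), math.exp(log_or + z * se))
        p = float(2 * stats.norm.sf(abs(log_or / se)))
        return EffectResults(
            log_or=log_or, se=se, ci=ci, p=p, n_used=n_used,
            scenario=self.scenario, ci_level=self.ci_level,
            exposure=exp_name, outcome=self.table.outcome,
            model=self, _smres=smres,
        )


def compare_cohorts(e1: EffectResults, e2: EffectResults) -> tuple[float, float]:
    """Normal z-test for a difference in log odds ratios from two
    independent samples; returns ``(z, two-sided p)``."""
    denom = math.hypot(e1.se, e2.se)
    if denom == 0:
        raise ValueError("both estimates have zero variance")
    z = (e1.log_or - e2.log_or) / denom
    return z, float(2 * stats.norm.sf(abs(z)))


@dataclass
class ScenarioBracket:
    """All three scenario fits plus the bracketing summary."""

    estimates: dict[str, EffectResults | FitError]
    bracket: tuple[float, float] | None   # [min, max] of the two adjusted log ORs
    sign_agreement: bool | None

    def summary(self) -> str:
        lines = ["Adjustment-scenario bracketing", "=" * 56]
        for sid in SCENARIOS:
            est = self.estimates.get(sid)
            if isinstance(est, EffectResults):
                lines.append(
                    f"{sid:27s} OR {est.odds_ratio:6.3f} "
                    f"({est.ci[0]:.3f}, {est.ci[1]:.3f})  p={est.p:.4g}  n={est.n_used}"
                )
            else:
                lines.append(f"{sid:27s} FAILED: {est}")
        if self.bracket is not None:
            lines.append(
                f"adjusted log-OR bracket [{self.bracket[0]:.4f}, {self.bracket[1]:.4f}]"
                f"   signs agree: {self.sign_agreement}"
            )
        return "\n".join(lines)


def run_scenarios(table: CohortTable, ci_level: float = 0.95) -> ScenarioBracket:
    """Fit all three adjustment scenarios on one table.

    The bracket is the interval spanned by the two adjusted log odds
    ratios; per-scenario fit errors are captured, not raised, so the
    remaining scenarios are still reported.
    """
    if not table.confounders:
        raise ValueError("role map declares no confounder")
    estimates: dict[str, EffectResults | FitError] = {}
    for sid in SCENARIOS:
        try:
            estimates[sid] = ExposureOutcomeModel(table, sid, ci_level).fit()
        except FitError as exc:
            estimates[sid] = exc
    adj = [estimates[s] for s in (CONFOUNDERS_ONLY, CONFOUNDERS_AND_MEDIATORS)]
    if all(isinstance(e, EffectResults) for e in adj):
        los = [e.log_or for e in adj]
        bracket = (min(los), max(los))
        sign_agreement = (los[0] > 0) == (los[1] > 0) if all(lo != 0 for lo in los) else None
    else:
        bracket, sign_agreement = None, None
    return ScenarioBracket(estimates, bracket, sign_agreement)
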