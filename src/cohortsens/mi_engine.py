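"""Chained-equations multiple imputation and Rubin's-rules pooling.

Fully conditional specification (FCS) for mixed variable types: binary
variables are imputed by logistic draws, continuous variables by predictive
mean matching (PMM, donor pool of 5 nearest predicted means), categorical
variables by multinomial-logit draws. Parameter uncertainty is propagated
by drawing imputation-model coefficients from the normal approximation at
the maximum-likelihood estimate. Auxiliary variables take part in every
imputation model via the predictor matrix but are excluded from analysis
models by their role.

Imputation-model fits carry a small ridge penalty (default 1e-5) so that
near-separated logistic steps stay finite; analysis models are never
penalised. The engine accepts a per-variable delta map shifting the linear
predictor of a binary variable at draw time — the hook used by the
Not-At-Random (delta-adjusted) analyses in :mod:`cohortsens.narmi`. With
all deltas zero the draw path is bit-for-bit the standard MAR imputation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .cohort import CohortTable, VarType
from .estimate import CONFOUNDERS_ONLY, ExposureOutcomeModel

__all__ = [
    "MiConfig",
    "ImputationSet",
    "PooledEstimate",
    "ImputationModelError",
    "impute",
    "pool",
    "pool_logistic",
]


class ImputationModelError(RuntimeError):
    """An imputation model could not be fit even after ridge stabilisation;
    names the variable and iteration."""


@dataclass(frozen=True)
class MiConfig:
    m: int = 50
    burnin: int = 10
    seed: int = 0
    ridge: float = 1e-5
    pmm_k: int = 5
    predictor_matrix: pd.DataFrame | None = None   # bool, zero diagonal
    include_missingness_indicators: bool = False

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.burnin < 1:
            raise ValueError("burnin must be >= 1")
        if self.predictor_matrix is not None:
            pm = self.predictor_matrix
            if any(pm.loc[v, v] for v in pm.index if v in pm.columns):
                raise ValueError("predictor matrix must have a zero diagonal")


@dataclass
class ImputationSet:
    """m completed tables plus chain diagnostics and the config echo."""

    tables: list[pd.DataFrame]
    mask: pd.DataFrame                      # True where originally missing
    variables: list
    chain_means: dict[str, np.ndarray]      # var -> (m, burnin) means of imputed cells
    config: MiConfig
    delta_map: dict[str, float] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.tables)

    def as_cohort_tables(self) -> list[CohortTable]:
        return [CohortTable(t.copy(), list(self.variables)) for t in self.tables]


# ---------------------------------------------------------------------------
# component fitters (imputation models only; ridge-stabilised)
def _ridge_logit(X: np.ndarray, y: np.ndarray, ridge: float,
                 max_iter: int = 50) -> tuple[np.ndarray, np.ndarray]:
    n, p = X.shape
    beta = np.zeros(p)
    I = np.eye(p)
    H = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu) + 1e-12
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * I
        step = np.linalg.solve(H, grad)
        nrm = np.linalg.norm(step)
        if nrm > 10:                      # damp huge separation-driven steps
            step *= 10 / nrm
        beta = beta + step
        if nrm < 1e-8:
            break
    cov = np.linalg.inv(H)
    return beta, cov


def _draw_coef(beta: np.ndarray, cov: np.ndarray, rng) -> np.ndarray:
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta)))
    return beta + L @ rng.standard_normal(len(beta))


def _impute_binary(Xo, yo, Xm, rng, ridge, delta=0.0):
    beta, cov = _ridge_logit(Xo, yo, ridge)
    bstar = _draw_coef(beta, cov, rng)
    eta = Xm @ bstar + delta
    return (rng.random(len(Xm)) < expit(np.clip(eta, -30, 30))).astype(float)


def _impute_pmm(Xo, yo, Xm, rng, ridge, k):
    n, p = Xo.shape
    A = Xo.T @ Xo + ridge * np.eye(p)
    betahat = np.linalg.solve(A, Xo.T @ yo)
    resid = yo - Xo @ betahat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / stats.chi2.rvs(df, random_state=rng)
    cov = sigma2 * np.linalg.inv(A)
    bstar = _draw_coef(betahat, cov, rng)
    eta_obs = Xo @ betahat
    eta_mis = Xm @ bstar
    # k nearest observed predicted means; draw one donor's observed value
    order = np.argsort(eta_obs)
    sorted_eta = eta_obs[order]
    pos = np.searchsorted(sorted_eta, eta_mis)
    out = np.empty(len(Xm))
    kk = min(k, n)
    for i, (p_i, e_i) in enumerate(zip(pos, eta_mis)):
        lo = max(0, p_i - kk)
        hi = min(n, p_i + kk)
        window = order[lo:hi]
        d = np.abs(eta_obs[window] - e_i)
        donors = window[np.argsort(d)[:kk]]
        out[i] = yo[donors[rng.integers(0, len(donors))]]
    return out


def _impute_multinomial(Xo, yo_codes, Xm, levels, rng, var, it):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(yo_codes, Xo).fit(disp=0, maxiter=200, method="lbfgs")
        params = np.asarray(res.params)                 # (p, J-1)
        cov = np.asarray(res.cov_params())
        flat = params.ravel(order="F")
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(flat)))
        draw = flat + L @ rng.standard_normal(len(flat))
        B = draw.reshape(params.shape, order="F")
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ImputationModelError(
            f"multinomial imputation model for {var!r} failed at iteration {it}"
        ) from exc
    logits = np.column_stack([np.zeros(len(Xm)), Xm @ B])
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(Xm))[:, None]
    idx = (u > cum).sum(axis=1)
    return np.asarray(levels, dtype=object)[idx]


# ---------------------------------------------------------------------------
def _encode_predictors(df: pd.DataFrame, names: list[str], types: dict) -> np.ndarray:
    """Numeric design for the given predictor columns, with intercept."""
    parts = [np.ones(len(df))]
    for name in names:
        col = df[name]
        if types[name] == VarType.CATEGORICAL:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:
                parts.append((col.astype(str) == level).astype(float).to_numpy())
        else:
            parts.append(col.to_numpy(dtype=float))
    return np.column_stack(parts)


def impute(
    table: CohortTable,
    config: MiConfig,
    delta_map: Mapping[str, float] | None = None,
) -> ImputationSet:
    """Run FCS imputation, returning ``config.m`` completed tables.

    Missing cells are initialised by random draws from the observed margins,
    then each incomplete variable is revisited for ``config.burnin``
    iterations in ascending order of missingness count, refitting its
    imputation model on the currently-complete data and drawing from the
    approximate posterior predictive. ``delta_map`` shifts the logistic
    linear predictor of the named binary variables at every draw (the
    Not-At-Random hook); omit it for standard MAR imputation.
    """
    delta_map = dict(delta_map or {})
    data = table.data
    mask = data.isna()
    types = {v.name: v.vtype for v in table.variables}
    for name in delta_map:
        if types.get(name) != VarType.BINARY:
            raise ValueError(f"delta adjustment requires a binary variable, got {name!r}")
    incomplete = [c for c in data.columns if mask[c].any()]
    # visit order: ascending missingness count
    incomplete.sort(key=lambda c: (int(mask[c].sum()), c))

    pm = config.predictor_matrix

    def predictors_for(var: str) -> list[str]:
        if pm is not None and var in pm.index:
            return [c for c in data.columns if c != var and bool(pm.loc[var].get(c, False))]
        return [c for c in data.columns if c != var]

    children = np.random.SeedSequence(config.seed).spawn(config.m)
    tables: list[pd.DataFrame] = []
    chain = {v: np.zeros((config.m, config.burnin)) for v in incomplete}

    for i in range(config.m):
        rng = np.random.default_rng(children[i])
        cur = data.copy()
        # initial fill from observed margins
        for var in incomplete:
            obs = data[var].dropna().to_numpy()
            miss_idx = mask[var].to_numpy().nonzero()[0]
            cur.iloc[miss_idx, cur.columns.get_loc(var)] = rng.choice(obs, size=len(miss_idx))
        for it in range(config.burnin):
            for var in incomplete:
                obs_rows = ~mask[var].to_numpy()
                mis_rows = mask[var].to_numpy()
                pred_names = predictors_for(var)
                X = _encode_predictors(cur, pred_names, types)
                if config.include_missingness_indicators:
                    inds = [mask[c].to_numpy(dtype=float) for c in incomplete if c != var]
                    if inds:
                        X = np.column_stack([X, *inds])
                Xo, Xm = X[obs_rows], X[mis_rows]
                vt = types[var]
                try:
                    if vt == VarType.BINARY:
                        yo = cur.loc[obs_rows, var].to_numpy(dtype=float)
                        vals = _impute_binary(Xo, yo, Xm, rng, config.ridge,
                                              delta=delta_map.get(var, 0.0))
                    elif vt == VarType.CONTINUOUS:
                        yo = cur.loc[obs_rows, var].to_numpy(dtype=float)
                        vals = _impute_pmm(Xo, yo, Xm, rng, config.ridge, config.pmm_k)
                    else:
                        levels = sorted(data[var].dropna().astype(str).unique())
                        codes = pd.Categorical(cur.loc[obs_rows, var].astype(str),
                                               categories=levels).codes
                        vals = _impute_multinomial(Xo, codes, Xm, levels, rng, var, it)
                except np.linalg.LinAlgError as exc:
                    raise ImputationModelError(
                        f"imputation model for {var!r} singular at iteration {it}"
                    ) from exc
                col_idx = cur.columns.get_loc(var)
                cur.iloc[mis_rows.nonzero()[0], col_idx] = vals
                if vt == VarType.CATEGORICAL:
                    ref = data[var].dropna().astype(str).value_counts().index[0]
                    chain[var][i, it] = float((cur.loc[mis_rows, var].astype(str) == ref).mean())
                else:
                    chain[var][i, it] = float(cur.loc[mis_rows, var].astype(float).mean())
        tables.append(cur)

    return ImputationSet(tables=tables, mask=mask, variables=list(table.variables),
                         chain_means=chain, config=config, delta_map=delta_map)


# ---------------------------------------------------------------------------
@dataclass
class PooledEstimate:
    """Rubin's-rules pooled log odds ratio across imputations."""

    qbar: float
    w: float          # within-imputation variance
    b: float          # between-imputation variance
    t: float          # total variance
    df: float         # Barnard–Rubin degrees of freedom
    m: int
    ci: tuple[float, float]   # odds-ratio scale
    p: float
    ci_level: float = 0.95

    @property
    def se(self) -> float:
        return math.sqrt(self.t)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.qbar)

    def summary(self) -> str:
        return (
            f"pooled log OR {self.qbar:.4f} (SE {self.se:.4f}), "
            f"OR {self.odds_ratio:.4f} "
            f"{100 * self.ci_level:.0f}% CI ({self.ci[0]:.4f}, {self.ci[1]:.4f}), "
            f"p={self.p:.4g}, m={self.m}, df={self.df:.1f}"
        )


def pool(per_imputation: list[tuple[float, float]], n_complete: int | None = None,
         n_params: int = 1, ci_level: float = 0.95) -> PooledEstimate:
    """Pool ``(estimate, se)`` pairs across imputations by Rubin's rules.

    Total variance ``t = w + (1 + 1/m) b``; degrees of freedom follow
    Barnard–Rubin when the complete-data sample size is supplied, else the
    classic large-sample formula.
    """
    if len(per_imputation) < 2:
        raise ValueError("pooling requires at least 2 imputations")
    q = np.array([e for e, _ in per_imputation], dtype=float)
    se = np.array([s for _, s in per_imputation], dtype=float)
    m = len(q)
    qbar = float(q.mean())
    w = float((se ** 2).mean())
    b = float(q.var(ddof=1))
    t = w + (1 + 1 / m) * b
    if b == 0:
        df = float("inf") if n_complete is None else float(n_complete - n_params)
    else:
        lam = (1 + 1 / m) * b / t
        df_old = (m - 1) / lam ** 2
        if n_complete is not None:
            dfcom = n_complete - n_params
            df_obs = (dfcom + 1) / (dfcom + 3) * dfcom * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        else:
            df = df_old
    tq = stats.t.ppf(0.5 + ci_level / 2, df) if math.isfinite(df) else stats.norm.ppf(0.5 + ci_level / 2)
    half = tq * math.sqrt(t)
    if math.isfinite(df):
        p = float(2 * stats.t.sf(abs(qbar) / math.sqrt(t), df)) if t > 0 else (1.0 if qbar == 0 else 0.0)
    else:
        p = float(2 * stats.norm.sf(abs(qbar) / math.sqrt(t))) if t > 0 else (1.0 if qbar == 0 else 0.0)
    return PooledEstimate(qbar=qbar, w=w, b=b, t=t, df=float(df), m=m,
                          ci=(math.exp(qbar - half), math.exp(qbar + half)),
                          p=p, ci_level=ci_level)


def pool_logistic(imps: ImputationSet, scenario=CONFOUNDERS_ONLY,
                  ci_level: float = 0.95) -> PooledEstimate:
    """Fit the analysis model on every completed table and pool."""
    pairs = []
    n_params = None
    n = None
    for ct in imps.as_cohort_tables():
        res = ExposureOutcomeModel(ct, scenario, ci_level).fit()
        pairs.append((res.log_or, res.se))
        n_params = res.model._X.shape[1]
        n = res.n_used
    return pool(pairs, n_complete=n, n_params=n_params, ci_level=ci_level)
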