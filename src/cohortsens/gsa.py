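"""Generalised sensitivity analysis with simulated pseudo-confounders.

The question answered here is the individual-level-data counterpart of the
E-value: how strongly would an unmeasured confounder U have to be
associated with both the exposure and the outcome — measured as partial
correlations given the adjustment set — before the observed
exposure–outcome association is explained away? The algorithm repeatedly
generates a pseudo-confounder calibrated to target partial correlations,
refits the analysis model including it, and traces the frontier of
(r_x, r_y) pairs at which the exposure statistic crosses the chosen target
(zero for nullifying the point estimate, the critical z for nullifying
significance). Observed covariates are benchmarked on the same scale so
the frontier can be judged against confounding strengths actually seen in
the data.

Scale conventions (these define the method here): partial correlations are
Pearson correlations of residuals. A covariate (or U) is residualized on
the conditioning set by least squares; the binary exposure and outcome are
residualized on the probability scale via their logistic fits (response
residual ``value - fitted probability``, which is exactly mean-zero when
the model has an intercept). r_x conditions on the adjustment set; r_y
conditions on the adjustment set plus the exposure.

The pseudo-confounder is a linear combination of the exposure residual,
the outcome residual and fresh Gaussian noise; its two loadings are
calibrated by damped fixed-point iteration. Because the combination is
linear, both achieved partial correlations are closed-form functions of
the loadings, so calibration costs a few scalar operations per step. A
binary U is obtained by thresholding the score at its median inside the
iteration, with achieved correlations always re-measured on the
thresholded variable; infeasible targets (e.g. r_x = 0.9 for a binary U)
then surface as a flagged non-convergence rather than an exception.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable
from .estimate import CONFOUNDERS_ONLY, build_design, scenario_covariates

__all__ = [
    "GsaConfig",
    "Benchmark",
    "FrontierPoint",
    "GsaFrontier",
    "CalibratedU",
    "GsaAnalysis",
    "benchmark_covariates",
    "calibrate_u",
    "frontier",
]


@dataclass(frozen=True)
class GsaConfig:
    u_type: str = "continuous"            # "continuous" | "binary"
    target: str = "nullify_point"         # "nullify_point" | "nullify_significance"
    alpha: float = 0.05
    grid: tuple = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
    k_draws: int = 50
    tol: float = 0.005
    max_iter: int = 200
    r_y_resolution: float = 0.005
    r_y_max: float = 0.90
    seed: int = 0

    def __post_init__(self):
        if self.u_type not in ("continuous", "binary"):
            raise ValueError(f"unknown u_type {self.u_type!r}")
        if self.target not in ("nullify_point", "nullify_significance"):
            raise ValueError(f"unknown target {self.target!r}")
        if any(not 0 <= g < 1 for g in self.grid):
            raise ValueError("grid values must be in [0, 1)")
        if self.k_draws < 1 or self.tol <= 0:
            raise ValueError("k_draws >= 1 and tol > 0 required")


@dataclass(frozen=True)
class Benchmark:
    name: str
    r_x: float
    r_y: float


@dataclass(frozen=True)
class FrontierPoint:
    r_x: float
    r_y: float          # NaN when no crossing within [0, r_y_max]
    stat: float         # averaged exposure z at the reported r_y
    converged: bool


@dataclass
class GsaFrontier:
    points: list[FrontierPoint]
    benchmarks: list[Benchmark]
    notice: str | None = None
    config: GsaConfig | None = None

    def summary(self) -> str:
        lines = ["Generalised sensitivity analysis frontier", "=" * 56]
        if self.notice:
            lines.append(f"NOTE: {self.notice}")
        lines.append(f"{'r_x':>8} {'r_y':>8} {'mean z':>8}  converged")
        for p in self.points:
            lines.append(f"{p.r_x:8.3f} {p.r_y:8.3f} {p.stat:8.3f}  {p.converged}")
        if self.benchmarks:
            lines.append("benchmarks (observed covariates):")
            for b in self.benchmarks:
                lines.append(f"  {b.name:24s} r_x={b.r_x: .3f}  r_y={b.r_y: .3f}")
        return "\n".join(lines)


@dataclass
class CalibratedU:
    u: np.ndarray
    achieved_r_x: float
    achieved_r_y: float
    converged: bool
    n_iter: int


def _logit_fitted(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    res = sm.Logit(y, Z).fit(disp=0, maxiter=200)
    return np.asarray(res.predict(Z))


def _orthonormal(Z: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(Z)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def _resid(v: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return v - Q @ (Q.T @ v)


def _corr(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    d = math.sqrt((u @ u) * (v @ v))
    return float(u @ v / d) if d > 0 else 0.0


def _partial_pair(y, x, Z, v) -> tuple[float, float]:
    """(r_x, r_y) of v: corr with exposure residual given Z, and with
    outcome residual given exposure + Z."""
    Qz = _orthonormal(Z)
    Zx = np.column_stack([Z, x])
    Qzx = _orthonormal(Zx)
    ex = x - _logit_fitted(x, Z)
    ey = y - _logit_fitted(y, Zx)
    return _corr(_resid(v, Qz), ex), _corr(_resid(v, Qzx), ey)


class _Context:
    """Precomputed residual machinery for one (table, scenario)."""

    def __init__(self, table: CohortTable, scenario, extra_cols: list[str] | None = None):
        self.table = table
        covariates = scenario_covariates(table, scenario) if isinstance(scenario, str) else list(scenario)
        self.scenario = scenario
        self.covariates = covariates
        y, X = build_design(table, covariates)
        self.index = X.index
        self.col_names = list(X.columns)
        self.y = y.to_numpy()
        self.X = X.to_numpy()           # [const, exposure, covariate cols...]
        self.x = X[table.exposure].to_numpy()
        zcols = [c for c in X.columns if c != table.exposure]
        self.Z = X[zcols].to_numpy()    # const + covariates
        self.Qz = _orthonormal(self.Z)
        self.Qzx = _orthonormal(np.column_stack([self.Z, self.x]))
        self.ex = self.x - _logit_fitted(self.x, self.Z)
        self.ey = self.y - _logit_fitted(self.y, np.column_stack([self.Z, self.x]))
        self.ex_s = self.ex / self.ex.std()
        self.ey_s = self.ey / self.ey.std()
        # residualized basis vectors and their inner products (closed-form
        # achieved correlations for a linear U)
        self.Pz = {k: _resid(v, self.Qz) for k, v in
                   (("ex", self.ex_s), ("ey", self.ey_s))}
        self.Pzx = {k: _resid(v, self.Qzx) for k, v in
                    (("ex", self.ex_s), ("ey", self.ey_s))}

    def achieved(self, u: np.ndarray) -> tuple[float, float]:
        return (_corr(_resid(u, self.Qz), self.ex),
                _corr(_resid(u, self.Qzx), self.ey))

    def refit_z(self, u: np.ndarray) -> float:
        """Exposure z-statistic from the analysis model refit including u.

        Uses a faintly ridge-stabilised Newton fit (1e-6) so that probes with
        an extremely outcome-informative pseudo-confounder — which would
        separate an unpenalised fit — still return a finite statistic.
        """
        from .mi_engine import _ridge_logit

        Xu = np.column_stack([self.X, u])
        beta, cov = _ridge_logit(Xu, self.y, ridge=1e-6)
        j = self.col_names.index(self.table.exposure)
        se = math.sqrt(max(cov[j, j], 1e-300))
        return float(beta[j] / se)


def _calibrate(ctx: _Context, r_x_t: float, r_y_t: float, u_type: str,
               rng: np.random.Generator, tol: float, max_iter: int,
               noise: np.ndarray | None = None) -> CalibratedU:
    n = len(ctx.y)
    e = rng.standard_normal(n) if noise is None else noise
    if u_type == "continuous":
        # closed-form achieved correlations via Gram matrices
        Pe_z, Pe_zx = _resid(e, ctx.Qz), _resid(e, ctx.Qzx)
        Bz = np.column_stack([ctx.Pz["ex"], ctx.Pz["ey"], Pe_z])
        Bzx = np.column_stack([ctx.Pzx["ex"], ctx.Pzx["ey"], Pe_zx])
        Gz, Gzx = Bz.T @ Bz, Bzx.T @ Bzx
        cx = Bz.T @ (ctx.ex - ctx.ex.mean())
        cy = Bzx.T @ (ctx.ey - ctx.ey.mean())
        nx = math.sqrt(((ctx.ex - ctx.ex.mean()) ** 2).sum())
        ny = math.sqrt(((ctx.ey - ctx.ey.mean()) ** 2).sum())

        def ach(a, b):
            w = np.array([a, b, 1.0])
            qz = float(w @ Gz @ w)
            qzx = float(w @ Gzx @ w)
            rx = float(w @ cx) / (math.sqrt(qz) * nx) if qz > 0 else 0.0
            ry = float(w @ cy) / (math.sqrt(qzx) * ny) if qzx > 0 else 0.0
            return rx, ry

        def build(a, b):
            return a * ctx.ex_s + b * ctx.ey_s + e
    else:
        def build(a, b):
            score = a * ctx.ex_s + b * ctx.ey_s + e
            return (score > np.median(score)).astype(float)

        def ach(a, b):
            return ctx.achieved(build(a, b))

    a, b = 2.0 * r_x_t, 2.0 * r_y_t
    step_a = step_b = 2.0
    prev_ea = prev_eb = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        rx, ry = ach(a, b)
        ea, eb = r_x_t - rx, r_y_t - ry
        if max(abs(ea), abs(eb)) < tol:
            break
        if ea * prev_ea < 0:
            step_a *= 0.5
        if eb * prev_eb < 0:
            step_b *= 0.5
        a += step_a * ea
        b += step_b * eb
        prev_ea, prev_eb = ea, eb
    u = build(a, b)
    rx, ry = ctx.achieved(u)
    converged = max(abs(r_x_t - rx), abs(r_y_t - ry)) < max(tol, 2e-3) * 2
    return CalibratedU(u=u, achieved_r_x=rx, achieved_r_y=ry,
                       converged=converged, n_iter=it)


class GsaAnalysis:
    """Generalised sensitivity analysis bound to one table and scenario."""

    def __init__(self, table: CohortTable, scenario=CONFOUNDERS_ONLY,
                 config: GsaConfig | None = None):
        self.config = config or GsaConfig()
        self.ctx = _Context(table, scenario)
        self.table = table

    # -- benchmarking ----------------------------------------------------
    def benchmarks(self, extra: list[str] | None = None) -> list[Benchmark]:
        """Benchmark each adjustment-set covariate by leave-one-out
        partialling; names in ``extra`` (columns of the table outside the
        adjustment set, e.g. an exposed ground-truth confounder) are
        benchmarked against the full adjustment set."""
        ctx = self.ctx
        out: list[Benchmark] = []
        cov_cols = [c for c in ctx.col_names if c not in ("const", ctx.table.exposure)]
        Xdf = pd.DataFrame(ctx.X, columns=ctx.col_names)
        for name in cov_cols:
            v = Xdf[name].to_numpy()
            if v.std() == 0:
                warnings.warn(f"covariate {name!r} is constant; benchmark skipped")
                continue
            Zm = Xdf[[c for c in ctx.col_names
                      if c not in (name, ctx.table.exposure)]].to_numpy()
            r_x, r_y = _partial_pair(ctx.y, ctx.x, Zm, v)
            out.append(Benchmark(name, r_x, r_y))
        for name in extra or []:
            v = self.table.data.loc[ctx.index, name].to_numpy(dtype=float)
            r_x, r_y = _partial_pair(ctx.y, ctx.x, ctx.Z, v)
            out.append(Benchmark(name, r_x, r_y))
        return out

    # -- calibration -----------------------------------------------------
    def calibrate(self, r_x_target: float, r_y_target: float,
                  seed: int | None = None) -> CalibratedU:
        if not (0 <= r_x_target <= 0.95 and 0 <= r_y_target <= 0.95):
            raise ValueError("targets must be in [0, 0.95]")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        return _calibrate(self.ctx, r_x_target, r_y_target, cfg.u_type,
                          rng, cfg.tol, cfg.max_iter)

    # -- frontier --------------------------------------------------------
    def _mean_z(self, r_x: float, r_y: float, noises: list[np.ndarray],
                rng: np.random.Generator) -> tuple[float, bool]:
        cfg = self.config
        zs, ok = [], True
        for e in noises:
            cal = _calibrate(self.ctx, r_x, r_y, cfg.u_type, rng,
                             cfg.tol, cfg.max_iter, noise=e)
            ok = ok and cal.converged
            zs.append(self.ctx.refit_z(cal.u))
        return float(np.mean(zs)), ok

    def frontier(self) -> GsaFrontier:
        """Trace the nullification frontier over the configured r_x grid.

        For each grid r_x, bisect on r_y until the draw-averaged exposure
        z-statistic crosses the target (0, or the critical value for the
        significance target); the frontier is monotonized post hoc
        (r_y non-increasing in r_x).
        """
        cfg = self.config
        ctx = self.ctx
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res0 = sm.Logit(ctx.y, ctx.X).fit(disp=0, maxiter=200)
        j = ctx.col_names.index(ctx.table.exposure)
        baseline_z = float(res0.params[j] / res0.bse[j])
        sign = 1.0 if baseline_z >= 0 else -1.0
        if cfg.target == "nullify_point":
            target = 0.0
            # a point estimate within ~2 SE of the null is already
            # statistically indistinguishable from the target
            threshold = 2.0
        else:
            target = sign * stats.norm.ppf(1 - cfg.alpha / 2)
            threshold = sign * target
        if sign * baseline_z <= threshold:
            return GsaFrontier(points=[FrontierPoint(0.0, 0.0, baseline_z, True)],
                               benchmarks=self.benchmarks(), config=cfg,
                               notice="baseline estimate already at target; degenerate frontier")

        points: list[FrontierPoint] = []
        for gi, r_x in enumerate(cfg.grid):
            ss = np.random.SeedSequence(cfg.seed, spawn_key=(gi,))
            rng = np.random.default_rng(ss)
            # common noise draws across bisection candidates
            noises = [rng.standard_normal(len(ctx.y)) for _ in range(cfg.k_draws)]
            lo, hi = 0.0, cfg.r_y_max
            z_hi, ok_hi = self._mean_z(r_x, hi, noises, rng)
            if sign * z_hi > sign * target:   # no crossing within range
                points.append(FrontierPoint(r_x, float("nan"), z_hi, ok_hi))
                continue
            z_mid, ok = baseline_z, True
            while hi - lo > cfg.r_y_resolution:
                mid = 0.5 * (lo + hi)
                z_mid, ok = self._mean_z(r_x, mid, noises, rng)
                if sign * z_mid > sign * target:
                    lo = mid
                else:
                    hi = mid
            # convergence flag reflects the final bracket's calibrations,
            # not the (possibly infeasible) upper probe
            points.append(FrontierPoint(r_x, 0.5 * (lo + hi), z_mid, ok))
        # monotonize: r_y non-increasing in r_x
        best = float("inf")
        mono: list[FrontierPoint] = []
        for p in points:
            if not math.isnan(p.r_y):
                best = min(best, p.r_y)
                mono.append(replace(p, r_y=best))
            else:
                mono.append(p)
        return GsaFrontier(points=mono, benchmarks=self.benchmarks(), config=cfg)


# -- spec-level functional surface ---------------------------------------
def benchmark_covariates(table: CohortTable, scenario=CONFOUNDERS_ONLY,
                         extra: list[str] | None = None) -> list[Benchmark]:
    return GsaAnalysis(table, scenario).benchmarks(extra=extra)


def calibrate_u(table: CohortTable, scenario, r_x_target: float, r_y_target: float,
                u_type: str = "continuous", seed: int = 0, tol: float = 0.005,
                max_iter: int = 200) -> CalibratedU:
    cfg = GsaConfig(u_type=u_type, tol=tol, max_iter=max_iter, seed=seed)
    return GsaAnalysis(table, scenario, cfg).calibrate(r_x_target, r_y_target, seed=seed)


def frontier(table: CohortTable, scenario=CONFOUNDERS_ONLY,
             config: GsaConfig | None = None) -> GsaFrontier:
    return GsaAnalysis(table, scenario, config).frontier()
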