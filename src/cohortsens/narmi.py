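"""Not-At-Random multiple imputation: delta adjustment and tipping points.

Standard multiple imputation assumes data are Missing At Random. When a
binary exposure or outcome may cause its own missingness (MNAR), that
assumption fails; the analyses here quantify how sensitive the pooled
estimate is to departures from MAR. A *conditional sensitivity parameter*
(CSP, a log-odds delta) is added to the linear predictor of the variable's
imputation model at every draw, expressing how records with missing data
differ from observed records conditional on everything else in the model.
A grid of deltas (default 0 to -2 by -0.25) is swept over the exposure,
the outcome, or both; each grid cell is imputed, analysed, and pooled by
Rubin's rules. Because conditional deltas are hard to interpret, each cell
also reports the implied *marginal sensitivity parameter* (MSP, the
unadjusted log-odds difference in the variable between originally-missing
and observed records) and the prevalence of the positive level among the
missing. The tipping point is the smallest-magnitude delta at which the
study's qualitative conclusion flips relative to the MAR anchor cell.

Missingness indicators are excluded from imputation models by default
(they are typically collinear and can produce implausible imputations);
``MiConfig.include_missingness_indicators`` re-enables them for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cohort import CohortTable, VarType
from .estimate import CONFOUNDERS_ONLY
from .mi_engine import ImputationSet, MiConfig, PooledEstimate, impute, pool_logistic

__all__ = [
    "DeltaGridSpec",
    "TippingCell",
    "TippingReport",
    "impute_delta",
    "csp_to_msp",
    "tipping_grid",
    "find_tipping",
]

DEFAULT_DELTAS = tuple(np.arange(0.0, -2.25, -0.25))

MODES = ("exposure_only", "outcome_only", "both")


@dataclass(frozen=True)
class DeltaGridSpec:
    """Grid of conditional sensitivity parameters (log-odds deltas)."""

    deltas: tuple = DEFAULT_DELTAS
    mode: str = "both"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not any(d == 0.0 for d in self.deltas):
            raise ValueError("delta grid must include 0 (the MAR anchor)")
        if not all(math.isfinite(d) for d in self.deltas):
            raise ValueError("deltas must be finite")

    def cells(self) -> list[tuple[float, float]]:
        """(delta_exposure, delta_outcome) pairs for the configured mode."""
        if self.mode == "exposure_only":
            return [(d, 0.0) for d in self.deltas]
        if self.mode == "outcome_only":
            return [(0.0, d) for d in self.deltas]
        return [(dx, dy) for dx in self.deltas for dy in self.deltas]


@dataclass
class TippingCell:
    """One grid cell: deltas applied, pooled analysis, MSP conversion."""

    csp_exposure: float
    csp_outcome: float
    pooled: PooledEstimate | Exception
    msp_exposure: float | None = None
    msp_outcome: float | None = None
    prev_missing_exposure: float | None = None
    prev_missing_outcome: float | None = None
    msp_flagged: bool = False     # continuity correction applied somewhere

    @property
    def ok(self) -> bool:
        return isinstance(self.pooled, PooledEstimate)


def impute_delta(
    table: CohortTable,
    config: MiConfig,
    delta_map: Mapping[str, float],
) -> ImputationSet:
    """Delta-adjusted FCS imputation.

    Identical to :func:`cohortsens.mi_engine.impute` except that every draw
    of a delta-mapped binary variable has its fitted linear predictor
    shifted by the variable's delta, at every iteration of every
    imputation. With all deltas zero the result is bitwise-identical to the
    standard MAR imputation under the same seed.
    """
    for name, d in delta_map.items():
        var = table.var(name)
        if var.vtype != VarType.BINARY:
            raise ValueError(f"delta adjustment unsupported for non-binary {name!r}")
        if not math.isfinite(d):
            raise ValueError(f"delta for {name!r} must be finite")
    return impute(table, config, delta_map=delta_map)


def csp_to_msp(imps: ImputationSet, variable: str) -> tuple[float, float, bool]:
    """Marginal sensitivity parameter implied by an imputation set.

    Per imputation: log-odds of the positive level among originally-missing
    records minus log-odds among observed records; averaged over
    imputations. Returns ``(msp, mean prevalence among missing, flagged)``
    where ``flagged`` marks a 0.5 continuity correction on an empty cell.
    """
    mask = imps.mask[variable].to_numpy()
    if not mask.any():
        raise ValueError(f"{variable!r} has no originally-missing cells")
    obs_vals = imps.tables[0].loc[~mask, variable].to_numpy(dtype=float)
    n_obs = len(obs_vals)
    k_obs = float(obs_vals.sum())
    msps, prevs = [], []
    flagged = False

    def _logit_counts(k: float, n: float) -> tuple[float, bool]:
        flag = k == 0 or k == n
        if flag:
            k, n = k + 0.5, n + 1.0
        return math.log(k / (n - k)), flag

    lo_obs, f1 = _logit_counts(k_obs, n_obs)
    flagged |= f1
    for t in imps.tables:
        miss_vals = t.loc[mask, variable].to_numpy(dtype=float)
        k_mis, n_mis = float(miss_vals.sum()), len(miss_vals)
        lo_mis, f2 = _logit_counts(k_mis, n_mis)
        flagged |= f2
        msps.append(lo_mis - lo_obs)
        prevs.append(k_mis / n_mis)
    return float(np.mean(msps)), float(np.mean(prevs)), flagged


def tipping_grid(
    table: CohortTable,
    config: MiConfig,
    grid: DeltaGridSpec,
    scenario=CONFOUNDERS_ONLY,
    ci_level: float = 0.95,
) -> list[TippingCell]:
    """Impute, analyse and pool every cell of the delta grid.

    Per-cell failures are captured in the cell rather than raised, so the
    remaining cells are still produced. Every cell uses the same master
    seed, so cell (0, 0) reproduces the standard-MI pooled estimate.
    """
    exposure, outcome = table.exposure, table.outcome
    cells: list[TippingCell] = []
    for dx, dy in grid.cells():
        delta_map = {exposure: dx, outcome: dy}
        try:
            imps = impute_delta(table, config, delta_map)
            pooled = pool_logistic(imps, scenario, ci_level)
            cell = TippingCell(csp_exposure=dx, csp_outcome=dy, pooled=pooled)
            if imps.mask[exposure].any():
                m, p, f = csp_to_msp(imps, exposure)
                cell.msp_exposure, cell.prev_missing_exposure = m, p
                cell.msp_flagged |= f
            if imps.mask[outcome].any():
                m, p, f = csp_to_msp(imps, outcome)
                cell.msp_outcome, cell.prev_missing_outcome = m, p
                cell.msp_flagged |= f
        except Exception as exc:   # isolate the failing cell
            cell = TippingCell(csp_exposure=dx, csp_outcome=dy, pooled=exc)
        cells.append(cell)
    return cells


@dataclass
class TippingReport:
    tipped: bool
    tipping_delta: tuple[float, float] | None
    criterion: str
    notice: str | None = None
    cells_examined: int = 0

    def summary(self) -> str:
        if self.notice:
            return f"tipping point: {self.notice}"
        if not self.tipped:
            return f"no tipping point within grid ({self.criterion})"
        dx, dy = self.tipping_delta
        return f"tipping point at (delta_exposure={dx}, delta_outcome={dy}) [{self.criterion}]"


def _ci_includes_null(cell: TippingCell) -> bool:
    lo, hi = cell.pooled.ci
    return lo <= 1.0 <= hi


def find_tipping(
    cells: list[TippingCell],
    criterion: str = "ci_includes_null",
    value: float = 0.0,
) -> TippingReport:
    """Locate the smallest-magnitude delta at which the conclusion flips.

    ``criterion`` is ``"ci_includes_null"`` (the pooled CI crosses OR = 1)
    or ``"point_crosses"`` (the pooled log-OR crosses ``value``). The flip
    is judged relative to the (0, 0) anchor cell; along mode ``both`` only
    the diagonal is scanned for the headline tipping delta.
    """
    if criterion == "ci_includes_null":
        flip = _ci_includes_null
    elif criterion == "point_crosses":
        def flip(cell: TippingCell) -> bool:
            return cell.pooled.qbar <= value
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    anchor = next((c for c in cells if c.csp_exposure == 0.0 and c.csp_outcome == 0.0 and c.ok), None)
    if anchor is None:
        return TippingReport(False, None, criterion, notice="no valid (0,0) anchor cell")
    base = flip(anchor)
    if base:
        return TippingReport(True, (0.0, 0.0), criterion,
                             notice="criterion already met at delta 0", cells_examined=1)
    # scan the diagonal (or the single axis) in increasing |delta|
    path = [c for c in cells if c.ok and (c.csp_exposure == c.csp_outcome
                                          or c.csp_exposure == 0.0 or c.csp_outcome == 0.0)]
    path.sort(key=lambda c: (max(abs(c.csp_exposure), abs(c.csp_outcome)),
                             abs(c.csp_exposure) + abs(c.csp_outcome)))
    for cell in path:
        if flip(cell) != base:
            return TippingReport(True, (cell.csp_exposure, cell.csp_outcome),
                                 criterion, cells_examined=len(path))
    return TippingReport(False, None, criterion, cells_examined=len(path))
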