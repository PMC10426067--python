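"""E-values: unmeasured-confounder strength needed to explain an association.

The E-value of a risk ratio ``RR >= 1`` is ``E = RR + sqrt(RR*(RR-1))``:
the minimum strength of association, on the risk-ratio scale, that a single
unmeasured confounder would need with both exposure and outcome to fully
account for the observed association. It inverts the bias-factor bound
``B(RR_EU, RR_UD) = RR_EU*RR_UD / (RR_EU + RR_UD - 1)`` along its diagonal,
i.e. the E-value solves ``RR = E^2 / (2E - 1)``. The same formula applied
to the ratio of an observed and a target risk ratio gives the confounding
strength needed to shift the estimate to that non-null target, and applied
to the confidence limit nearer the null it gives the strength needed to
make the association non-significant.

Odds ratios from a logistic model are mapped to approximate risk ratios
first: for a common outcome (prevalence above roughly 15%) ``RR ~ sqrt(OR)``;
for a rare outcome the odds ratio approximates the risk ratio directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "approx_rr",
    "evalue_point",
    "evalue_nonnull",
    "evalue_ci",
    "bias_bound",
    "EvalueResult",
    "evalue_analysis",
]


def approx_rr(odds_ratio: float, outcome_common: bool = True) -> float:
    """Approximate risk ratio for an odds ratio.

    ``sqrt(OR)`` when the outcome is common, the identity otherwise.
    Values below 1 are returned as-is (invert downstream if needed).
    """
    if odds_ratio <= 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    return math.sqrt(odds_ratio) if outcome_common else float(odds_ratio)


def evalue_point(rr: float) -> float:
    """E-value moving risk ratio ``rr`` to the null.

    Protective estimates (``rr < 1``) are inverted first, so the result is
    always >= 1.
    """
    if rr <= 0:
        raise ValueError(f"risk ratio must be positive, got {rr}")
    if rr < 1:
        rr = 1.0 / rr
    return rr + math.sqrt(rr * (rr - 1.0))


def evalue_nonnull(rr_obs: float, rr_true: float) -> float:
    """E-value shifting an observed risk ratio to a non-null target."""
    if rr_obs <= 0 or rr_true <= 0:
        raise ValueError("risk ratios must be positive")
    r = max(rr_obs / rr_true, rr_true / rr_obs)
    return evalue_point(r)


def evalue_ci(
    ci_limit_or: float, point_or: float, outcome_common: bool = True
) -> float:
    """E-value moving the confidence limit nearer the null to the null.

    Returns 1 when the interval already spans the null (no confounding is
    needed to make the association non-significant).
    """
    if ci_limit_or <= 0 or point_or <= 0:
        raise ValueError("odds ratios must be positive")
    # the limit spans the null when it sits on the other side of 1 from the point
    if (point_or >= 1 and ci_limit_or <= 1) or (point_or <= 1 and ci_limit_or >= 1):
        return 1.0
    return evalue_point(approx_rr(ci_limit_or, outcome_common))


def bias_bound(rr_eu: float, rr_ud: float) -> float:
    """Maximal multiplicative bias from a confounder of strengths
    ``(rr_eu, rr_ud)``: ``B = rr_eu*rr_ud / (rr_eu + rr_ud - 1)``."""
    if rr_eu < 1 or rr_ud < 1:
        raise ValueError("bias-bound inputs must be >= 1 (invert upstream)")
    return rr_eu * rr_ud / (rr_eu + rr_ud - 1.0)


@dataclass(frozen=True)
class EvalueResult:
    """E-value battery for one fitted odds ratio."""

    input_or: float
    outcome_common: bool
    rr_approx: float
    e_point: float
    e_ci: float | None = None
    e_nonnull: float | None = None
    nonnull_target_or: float | None = None

    def summary(self) -> str:
        lines = [
            "E-value analysis",
            "=" * 40,
            f"odds ratio        {self.input_or:.3f}"
            + ("  (common-outcome sqrt transform)" if self.outcome_common else ""),
            f"approx risk ratio {self.rr_approx:.4f}",
            f"E-value (point)   {self.e_point:.2f}",
        ]
        if self.e_ci is not None:
            lines.append(f"E-value (CI)      {self.e_ci:.2f}")
        if self.e_nonnull is not None:
            lines.append(
                f"E-value (to OR {self.nonnull_target_or:.3f})  {self.e_nonnull:.2f}"
            )
        return "\n".join(lines)


def evalue_analysis(
    odds_ratio: float,
    ci: tuple[float, float] | None = None,
    outcome_common: bool = True,
    nonnull_target_or: float | None = None,
) -> EvalueResult:
    """Full E-value battery for an odds ratio with optional CI and target.

    The CI E-value uses the limit nearer the null; the non-null E-value
    transforms both the observed and the target odds ratio before forming
    their ratio.
    """
    rr = approx_rr(odds_ratio, outcome_common)
    e_point = evalue_point(rr)
    e_ci = None
    if ci is not None:
        lo, hi = ci
        limit = lo if odds_ratio >= 1 else hi
        e_ci = evalue_ci(limit, odds_ratio, outcome_common)
    e_nonnull = None
    if nonnull_target_or is not None:
        e_nonnull = evalue_nonnull(rr, approx_rr(nonnull_target_or, outcome_common))
    return EvalueResult(
        input_or=float(odds_ratio),
        outcome_common=outcome_common,
        rr_approx=rr,
        e_point=e_point,
        e_ci=e_ci,
        e_nonnull=e_nonnull,
        nonnull_target_or=nonnull_target_or,
    )
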