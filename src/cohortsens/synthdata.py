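"""Synthetic cohort generation with known causal structure.

The generator emulates a prospective birth-cohort setting: a binary exposure
(regular attendance at a place of worship, prevalence ~0.14), a binary
outcome (ever having donated blood, prevalence ~0.30), a block of measured
confounders, a variable measured at two timepoints that is both a confounder
(time 1) and a mediator (time 3) of the exposure–outcome relation, an
unmeasured confounder U, and exposure-caused auxiliary variables (smoking,
alcohol use, depression) that drive missingness. Missingness is imposed per
variable from logistic models on observed covariates/auxiliaries (the MAR
part) plus an optional self-dependence delta on the variable's own value
(the MNAR part).

All binary variables are generated from logit-link Bernoulli models, so the
log-odds-ratio estimand is coherent across every downstream analysis. One
master seed spawns independent per-stage substreams, so adding a stage never
perturbs draws in earlier stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable, Role, SpecificationError, Variable, VarType

__all__ = [
    "Bernoulli",
    "Categorical",
    "Normal",
    "LinearPredictor",
    "MissingnessModel",
    "CohortSpec",
    "TruthRecord",
    "generate",
    "impose_missingness",
    "simulate",
    "default_spec",
    "selection_bias_spec",
]

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# distributions for the exogenous confounder block
@dataclass(frozen=True)
class Bernoulli:
    p: float

    def validate(self, name):
        if not 0.0 < self.p < 1.0:
            raise SpecificationError(f"{name}: Bernoulli p must be in (0,1), got {self.p}")

    def draw(self, rng, n):
        return rng.binomial(1, self.p, size=n).astype(float)

    vtype = VarType.BINARY


@dataclass(frozen=True)
class Categorical:
    levels: tuple
    probs: tuple

    def validate(self, name):
        if len(self.levels) != len(self.probs) or len(self.levels) < 2:
            raise SpecificationError(f"{name}: levels/probs mismatch")
        if any(p <= 0 for p in self.probs) or abs(sum(self.probs) - 1.0) > 1e-9:
            raise SpecificationError(f"{name}: categorical probs must be positive and sum to 1")

    def draw(self, rng, n):
        idx = rng.choice(len(self.levels), size=n, p=np.asarray(self.probs, dtype=float))
        return np.asarray(self.levels, dtype=object)[idx]

    vtype = VarType.CATEGORICAL


@dataclass(frozen=True)
class Normal:
    mu: float
    sd: float

    def validate(self, name):
        if not self.sd > 0:
            raise SpecificationError(f"{name}: Normal sd must be > 0, got {self.sd}")

    def draw(self, rng, n):
        return rng.normal(self.mu, self.sd, size=n)

    vtype = VarType.CONTINUOUS


@dataclass(frozen=True)
class LinearPredictor:
    """Log-odds linear predictor ``intercept + sum(coef * term)``.

    Coefficient keys are variable names; a key ``"var=level"`` refers to the
    indicator that categorical ``var`` equals ``level``.
    """

    intercept: float
    coefs: Mapping[str, float] = field(default_factory=dict)

    def referenced(self) -> set[str]:
        return {k.split("=", 1)[0] for k in self.coefs}

    def eval(self, frame: Mapping[str, np.ndarray], n: int) -> np.ndarray:
        lp = np.full(n, self.intercept, dtype=float)
        if self.intercept == NEG_INF:
            return lp
        for key, coef in self.coefs.items():
            if "=" in key:
                var, level = key.split("=", 1)
                term = (np.asarray(frame[var]) == level).astype(float)
            else:
                term = np.asarray(frame[key], dtype=float)
            lp += coef * term
        return lp


@dataclass(frozen=True)
class MissingnessModel:
    """Per-variable missingness: MAR part on observed variables, plus an
    optional MNAR delta multiplying the variable's own value."""

    model: LinearPredictor
    mnar_delta: float = 0.0


@dataclass
class CohortSpec:
    """Full data-generating specification for one synthetic cohort."""

    n: int
    confounders: list[tuple[str, object]]
    exposure_model: LinearPredictor
    outcome_model: LinearPredictor
    mediator_t1_model: LinearPredictor
    mediator_t3_model: LinearPredictor
    auxiliary_models: dict[str, LinearPredictor]
    missingness_models: dict[str, MissingnessModel] = field(default_factory=dict)
    u_dist: object = Normal(0.0, 1.0)
    exposure_name: str = "attend"
    outcome_name: str = "donate"
    mediator_t1_name: str = "married_t1"
    mediator_t3_name: str = "married_t3"
    u_name: str = "u"
    expose_u: bool = False
    expose_mediator_t1: bool = False

    @property
    def beta_xy_true(self) -> float:
        return float(self.outcome_model.coefs.get(self.exposure_name, 0.0))

    def declared_names(self) -> list[str]:
        names = [name for name, _ in self.confounders]
        names += [self.u_name, self.mediator_t1_name, self.exposure_name,
                  self.mediator_t3_name, *self.auxiliary_models, self.outcome_name]
        return names

    def validate(self) -> None:
        if self.n < 1:
            raise SpecificationError("n must be >= 1")
        for name, dist in self.confounders:
            dist.validate(name)
        self.u_dist.validate(self.u_name)
        declared = set(self.declared_names())
        if len(declared) != len(self.declared_names()):
            raise SpecificationError("duplicate variable names in spec")
        models = {
            self.mediator_t1_name: self.mediator_t1_model,
            self.exposure_name: self.exposure_model,
            self.mediator_t3_name: self.mediator_t3_model,
            self.outcome_name: self.outcome_model,
            **self.auxiliary_models,
        }
        for name, model in models.items():
            bad = model.referenced() - declared
            if bad:
                raise SpecificationError(f"model for {name!r} references undeclared {sorted(bad)}")
        for name, mm in self.missingness_models.items():
            if name not in declared:
                raise SpecificationError(f"missingness model for undeclared variable {name!r}")
            bad = mm.model.referenced() - declared
            if bad:
                raise SpecificationError(
                    f"missingness model for {name!r} references undeclared {sorted(bad)}")


@dataclass
class TruthRecord:
    """Ground truth retained for downstream oracles."""

    beta_xy_true: float
    u_values: np.ndarray
    mediator_t1_values: np.ndarray
    complete_table: CohortTable
    implied_missing_rate: pd.Series | None = None
    realized_missing_rate: pd.Series | None = None


# named stages, fixed order: appending a stage never shifts earlier streams
_STAGES = ("confounders", "u", "mediator_t1", "exposure", "mediator_t3",
           "auxiliaries", "outcome", "missingness")


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(child) for name, child in zip(_STAGES, children)}


def generate(spec: CohortSpec, seed: int) -> tuple[CohortTable, TruthRecord]:
    """Draw a complete cohort in causal order.

    Order: confounders → U → time-1 mediator → exposure → time-3 mediator and
    auxiliaries → outcome. U (and the time-1 mediator) are stored in the
    :class:`TruthRecord` and excluded from the table unless the spec's
    ``expose_u`` / ``expose_mediator_t1`` flags are set.
    """
    spec.validate()
    rngs = _stage_rngs(seed)
    n = spec.n
    frame: dict[str, np.ndarray] = {}

    rng_c = rngs["confounders"]
    for name, dist in spec.confounders:
        frame[name] = dist.draw(rng_c, n)
    frame[spec.u_name] = spec.u_dist.draw(rngs["u"], n)

    def draw_binary(name, model, rng):
        p = expit(model.eval(frame, n))
        frame[name] = (rng.random(n) < p).astype(float)

    draw_binary(spec.mediator_t1_name, spec.mediator_t1_model, rngs["mediator_t1"])
    draw_binary(spec.exposure_name, spec.exposure_model, rngs["exposure"])
    draw_binary(spec.mediator_t3_name, spec.mediator_t3_model, rngs["mediator_t3"])
    rng_a = rngs["auxiliaries"]
    for name, model in spec.auxiliary_models.items():
        draw_binary(name, model, rng_a)
    draw_binary(spec.outcome_name, spec.outcome_model, rngs["outcome"])

    variables = []
    for name, dist in spec.confounders:
        variables.append(Variable(name, dist.vtype, Role.CONFOUNDER))
    if spec.expose_u:
        variables.append(Variable(spec.u_name, spec.u_dist.vtype, Role.OTHER))
    if spec.expose_mediator_t1:
        variables.append(Variable(spec.mediator_t1_name, VarType.BINARY, Role.CONFOUNDER))
    variables.append(Variable(spec.exposure_name, VarType.BINARY, Role.EXPOSURE))
    variables.append(Variable(spec.mediator_t3_name, VarType.BINARY, Role.CONFOUNDER_OR_MEDIATOR))
    for name in spec.auxiliary_models:
        variables.append(Variable(name, VarType.BINARY, Role.AUXILIARY))
    variables.append(Variable(spec.outcome_name, VarType.BINARY, Role.OUTCOME))

    data = pd.DataFrame({v.name: frame[v.name] for v in variables})
    table = CohortTable(data, variables)
    truth = TruthRecord(
        beta_xy_true=spec.beta_xy_true,
        u_values=frame[spec.u_name].copy(),
        mediator_t1_values=frame[spec.mediator_t1_name].copy(),
        complete_table=table.copy(),
    )
    return table, truth


def impose_missingness(
    table: CohortTable,
    spec: CohortSpec,
    seed: int,
    truth: TruthRecord | None = None,
) -> CohortTable:
    """Delete entries per the spec's missingness models; input untouched.

    Each variable's deletion indicator is Bernoulli with probability
    ``expit(MAR linear predictor + mnar_delta * own value)`` evaluated on the
    complete (pre-deletion) values. An intercept of ``-inf`` yields
    probability zero, i.e. a fully observed variable.
    """
    if table.missing_mask().to_numpy().any():
        raise SpecificationError("impose_missingness requires a complete table")
    rng = _stage_rngs(seed)["missingness"]
    out = table.copy()
    n = table.n
    frame = {name: table.data[name].to_numpy() for name in table.data.columns}
    implied, realized = {}, {}
    for name in table.data.columns:  # declared column order: deterministic
        mm = spec.missingness_models.get(name)
        if mm is None:
            continue
        lp = mm.model.eval(frame, n)
        if mm.mnar_delta != 0.0:
            lp = lp + mm.mnar_delta * np.asarray(frame[name], dtype=float)
        p = np.where(np.isneginf(lp), 0.0, expit(lp))
        drop = rng.random(n) < p
        col = out.data[name].copy()
        col[drop] = np.nan if col.dtype != object else None
        out.data[name] = col
        implied[name] = float(np.mean(p))
        realized[name] = float(np.mean(drop))
    if truth is not None:
        truth.implied_missing_rate = pd.Series(implied, dtype=float)
        truth.realized_missing_rate = pd.Series(realized, dtype=float)
    return out


def simulate(spec: CohortSpec, seed: int) -> tuple[CohortTable, TruthRecord]:
    """Generate a complete cohort and impose missingness in one call."""
    complete, truth = generate(spec, seed)
    observed = impose_missingness(complete, spec, seed, truth)
    return observed, truth


# ---------------------------------------------------------------------------
# default study-scale specification
def default_spec(
    preset: str = "mothers",
    n: int = 13_000,
    beta_xy: float = math.log(1.5),
    u_coef_exposure: float = 0.4,
    u_coef_outcome: float = 0.3,
    mediator_confounding: float = 0.35,
    mnar_delta_exposure: float = 0.0,
    mnar_delta_outcome: float = 0.0,
    expose_u: bool = False,
) -> CohortSpec:
    """Study-scale default cohort specification.

    The mother-like preset targets exposure prevalence ~0.14, outcome
    prevalence ~0.30 and ~12% missingness in exposure and outcome; the
    partner-like preset raises missingness to ~40%. ``mediator_confounding``
    is the time-1 mediator's coefficient in the exposure model (set 0 for a
    pure mediator). MNAR deltas are the self-dependence coefficients of the
    exposure/outcome missingness models (0 = MAR).
    """
    if preset not in ("mothers", "partners"):
        raise SpecificationError(f"unknown preset {preset!r}")
    # intercepts calibrated once at n=400k against the target marginal rates
    confounders = [
        ("age", Normal(0.0, 1.0)),           # standardized age
        ("edu", Categorical(("low", "mid", "high"), (0.3, 0.5, 0.2))),
        ("employed", Bernoulli(0.7)),
    ]
    mediator_t1 = LinearPredictor(0.30, {"age": 0.3, "edu=high": 0.3})
    exposure = LinearPredictor(
        -2.28,
        {"age": 0.25, "edu=high": 0.4, "employed": 0.1,
         "married_t1": mediator_confounding, "u": u_coef_exposure},
    )
    mediator_t3 = LinearPredictor(-1.30, {"married_t1": 2.5, "attend": 0.5})
    auxiliaries = {
        "smoker": LinearPredictor(-0.85, {"attend": -0.5, "age": -0.2}),
        "alcohol": LinearPredictor(-0.30, {"attend": -0.4, "age": 0.1}),
        "depressed": LinearPredictor(-1.50, {"attend": -0.2, "age": -0.1}),
    }
    outcome = LinearPredictor(
        -1.25,
        {"attend": beta_xy, "age": 0.2, "edu=high": 0.3, "employed": 0.15,
         "married_t3": 0.25, "u": u_coef_outcome},
    )
    # missingness driven by the exposure-caused auxiliaries (MAR part)
    if preset == "mothers":
        m_int_xy, m_int_cov = -2.37, -2.60
    else:
        m_int_xy, m_int_cov = -0.76, -1.05
    missingness = {
        "attend": MissingnessModel(
            LinearPredictor(m_int_xy, {"smoker": 0.5, "depressed": 0.4, "alcohol": 0.3}),
            mnar_delta=mnar_delta_exposure,
        ),
        "donate": MissingnessModel(
            LinearPredictor(m_int_xy, {"smoker": 0.5, "depressed": 0.4, "alcohol": 0.3}),
            mnar_delta=mnar_delta_outcome,
        ),
        "edu": MissingnessModel(LinearPredictor(m_int_cov, {"smoker": 0.3})),
        "employed": MissingnessModel(LinearPredictor(m_int_cov, {"depressed": 0.3})),
        "married_t3": MissingnessModel(LinearPredictor(m_int_cov, {"alcohol": 0.2})),
    }
    return CohortSpec(
        n=n,
        confounders=confounders,
        exposure_model=exposure,
        outcome_model=outcome,
        mediator_t1_model=mediator_t1,
        mediator_t3_model=mediator_t3,
        auxiliary_models=auxiliaries,
        missingness_models=missingness,
        expose_u=expose_u,
    )


def selection_bias_spec(n: int = 30_000, beta_xy: float = math.log(1.5)) -> CohortSpec:
    """Cohort specification whose missingness visibly biases the
    complete-case odds ratio while remaining recoverable by imputation.

    Selection that factorizes into an exposure part times an outcome part
    leaves the covariate-conditional odds ratio untouched, so a scenario
    meant to demonstrate complete-case selection bias needs
    non-multiplicative selection. Here exposure missingness depends jointly
    on an exposure-caused auxiliary (heavy alcohol use) and on the outcome
    itself — both observed, so the data are Missing At Random and multiple
    imputation with the auxiliaries in the predictor set recovers the
    full-data estimate, while the complete-case fit is biased away from it.
    """
    spec = default_spec(n=n, beta_xy=beta_xy, u_coef_exposure=0.0, u_coef_outcome=0.0)
    spec.auxiliary_models["alcohol"] = LinearPredictor(-0.2, {"attend": -2.0, "age": 0.1})
    spec.missingness_models = {
        "attend": MissingnessModel(
            LinearPredictor(-3.0, {"alcohol": 2.2, "donate": 2.2})),
        "donate": MissingnessModel(
            LinearPredictor(-1.8, {"alcohol": 1.2, "smoker": 0.5})),
    }
    return spec
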