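"""Orchestration of the full sensitivity-analysis battery.

One :class:`RunConfig` (built directly or loaded from YAML) drives the
whole pipeline: simulate or load a cohort, fit the three adjustment
scenarios, compute E-values for each adjusted estimate, run the
generalised sensitivity analysis, standard multiple imputation, and the
Not-At-Random tipping grids. Stages are isolated — a failure in one stage
is recorded in its report section and the remaining stages still run. All
randomness flows from the master seed through named substreams recorded
in the provenance block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortTable
from .estimate import (CONFOUNDERS_AND_MEDIATORS, CONFOUNDERS_ONLY, SCENARIOS,
                       EffectResults, run_scenarios)
from .evalue import evalue_analysis
from .gsa import GsaAnalysis, GsaConfig
from .mi_engine import MiConfig, impute, pool_logistic
from .narmi import DeltaGridSpec, find_tipping, tipping_grid
from .synthdata import default_spec, simulate

__all__ = ["RunConfig", "BatteryReport", "run_battery", "write_report", "load_config"]

_STAGE_NAMES = ("simulate", "estimate", "evalue", "gsa", "mi", "narmi")


@dataclass
class RunConfig:
    """Structured configuration for one battery run."""

    table_csv: str | None = None            # path to CSV + .roles.json sidecar
    synth_preset: str | None = "mothers"    # used when table_csv is None
    synth_n: int = 13_000
    stages: tuple = _STAGE_NAMES
    ci_level: float = 0.95
    outcome_common: bool = True
    gsa: GsaConfig = field(default_factory=lambda: GsaConfig(grid=(0.05, 0.10, 0.15), k_draws=10))
    mi: MiConfig = field(default_factory=lambda: MiConfig(m=50, burnin=10))
    narmi_grid: DeltaGridSpec = field(default_factory=DeltaGridSpec)
    narmi_scenario: str = CONFOUNDERS_ONLY
    seed: int = 0

    def __post_init__(self):
        bad = set(self.stages) - set(_STAGE_NAMES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")
        if not self.stages:
            raise ValueError("at least one stage must be enabled")

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (tuple, list)):
                return [enc(v) for v in o]
            if isinstance(o, pd.DataFrame):
                return o.to_dict()
            return o
        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (flat keys; nested gsa/mi/narmi maps)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("table_csv", "synth_preset", "synth_n", "ci_level",
                "outcome_common", "seed", "narmi_scenario"):
        if key in raw:
            kwargs[key] = raw[key]
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    if "gsa" in raw:
        g = dict(raw["gsa"])
        if "grid" in g:
            g["grid"] = tuple(g["grid"])
        kwargs["gsa"] = GsaConfig(**g)
    if "mi" in raw:
        kwargs["mi"] = MiConfig(**raw["mi"])
    if "narmi" in raw:
        nr = dict(raw["narmi"])
        if "deltas" in nr:
            nr["deltas"] = tuple(nr["deltas"])
        kwargs["narmi_grid"] = DeltaGridSpec(**nr)
    return RunConfig(**kwargs)


@dataclass
class BatteryReport:
    """Per-stage result tables plus provenance."""

    sections: dict[str, pd.DataFrame]
    errors: dict[str, str]
    provenance: dict

    @property
    def failed(self) -> bool:
        return bool(self.errors)

    def summary(self) -> str:
        lines = [f"Sensitivity-analysis battery (seed {self.provenance['seed']})", "=" * 60]
        for name, df in self.sections.items():
            lines.append(f"[{name}] {len(df)} rows")
            lines.append(df.to_string(index=False, max_rows=12))
        for name, err in self.errors.items():
            lines.append(f"[{name}] FAILED: {err.splitlines()[-1]}")
        return "\n".join(lines)


def _estimates_frame(bracket) -> pd.DataFrame:
    rows = []
    for sid in SCENARIOS:
        est = bracket.estimates.get(sid)
        if isinstance(est, EffectResults):
            rows.append({
                "scenario": sid, "log_or": est.log_or, "se": est.se,
                "or": est.odds_ratio, "ci_low": est.ci[0], "ci_high": est.ci[1],
                "p": est.p, "n_used": est.n_used,
            })
        else:
            rows.append({"scenario": sid, "error": str(est)})
    return pd.DataFrame(rows)


def run_battery(config: RunConfig) -> BatteryReport:
    """Execute the enabled stages in dependency order."""
    t0 = time.time()
    sections: dict[str, pd.DataFrame] = {}
    errors: dict[str, str] = {}
    seed_root = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(child.generate_state(1)[0] % (2 ** 31))
                   for name, child in zip(_STAGE_NAMES, seed_root.spawn(len(_STAGE_NAMES)))}

    # -- input table -----------------------------------------------------
    if config.table_csv is not None:
        table = CohortTable.from_csv(config.table_csv)
        truth = None
    else:
        spec = default_spec(preset=config.synth_preset or "mothers", n=config.synth_n)
        table, truth = simulate(spec, stage_seeds["simulate"])
        if "simulate" in config.stages:
            sections["simulate"] = pd.DataFrame({
                "variable": table.data.columns,
                "role": [v.role for v in table.variables],
                "missing_frac": table.missing_fraction().to_numpy(),
            })

    bracket = None
    if "estimate" in config.stages:
        try:
            bracket = run_scenarios(table, config.ci_level)
            sections["estimate"] = _estimates_frame(bracket)
        except Exception:
            errors["estimate"] = traceback.format_exc()

    adjusted: dict[str, EffectResults] = {}
    if bracket is not None:
        for sid in (CONFOUNDERS_ONLY, CONFOUNDERS_AND_MEDIATORS):
            est = bracket.estimates.get(sid)
            if isinstance(est, EffectResults):
                adjusted[sid] = est

    if "evalue" in config.stages:
        try:
            rows = []
            for sid, est in adjusted.items():
                ev = evalue_analysis(est.odds_ratio, ci=est.ci,
                                     outcome_common=config.outcome_common)
                rows.append({"scenario": sid, "or": ev.input_or,
                             "rr_approx": ev.rr_approx, "e_point": ev.e_point,
                             "e_ci": ev.e_ci})
            sections["evalue"] = pd.DataFrame(rows)
        except Exception:
            errors["evalue"] = traceback.format_exc()

    if "gsa" in config.stages:
        try:
            gcfg = dataclasses.replace(config.gsa, seed=stage_seeds["gsa"])
            fr = GsaAnalysis(table, CONFOUNDERS_ONLY, gcfg).frontier()
            rows = [{"r_x": p.r_x, "r_y": p.r_y, "mean_z": p.stat,
                     "converged": p.converged} for p in fr.points]
            sections["gsa"] = pd.DataFrame(rows)
            sections["gsa_benchmarks"] = pd.DataFrame(
                [{"covariate": b.name, "r_x": b.r_x, "r_y": b.r_y} for b in fr.benchmarks])
        except Exception:
            errors["gsa"] = traceback.format_exc()

    imps = None
    if "mi" in config.stages:
        try:
            mcfg = dataclasses.replace(config.mi, seed=stage_seeds["mi"])
            imps = impute(table, mcfg)
            rows = []
            for sid in adjusted or [CONFOUNDERS_ONLY]:
                pooled = pool_logistic(imps, sid, config.ci_level)
                rows.append({"scenario": sid, "log_or": pooled.qbar, "se": pooled.se,
                             "or": pooled.odds_ratio, "ci_low": pooled.ci[0],
                             "ci_high": pooled.ci[1], "p": pooled.p, "m": pooled.m})
            sections["mi"] = pd.DataFrame(rows)
        except Exception:
            errors["mi"] = traceback.format_exc()

    if "narmi" in config.stages:
        try:
            ncfg = dataclasses.replace(config.mi, seed=stage_seeds["narmi"])
            cells = tipping_grid(table, ncfg, config.narmi_grid, config.narmi_scenario,
                                 config.ci_level)
            rows = []
            for c in cells:
                row = {"csp_exposure": c.csp_exposure, "csp_outcome": c.csp_outcome}
                if c.ok:
                    row.update({"log_or": c.pooled.qbar, "se": c.pooled.se,
                                "ci_low": c.pooled.ci[0], "ci_high": c.pooled.ci[1],
                                "p": c.pooled.p,
                                "msp_exposure": c.msp_exposure,
                                "msp_outcome": c.msp_outcome,
                                "prev_missing_exposure": c.prev_missing_exposure,
                                "prev_missing_outcome": c.prev_missing_outcome,
                                "msp_flagged": c.msp_flagged})
                else:
                    row["error"] = str(c.pooled)
                rows.append(row)
            sections["narmi"] = pd.DataFrame(rows)
            report = find_tipping(cells)
            sections["narmi_tipping"] = pd.DataFrame([{
                "tipped": report.tipped,
                "delta_exposure": None if report.tipping_delta is None else report.tipping_delta[0],
                "delta_outcome": None if report.tipping_delta is None else report.tipping_delta[1],
                "criterion": report.criterion,
                "notice": report.notice,
            }])
        except Exception:
            errors["narmi"] = traceback.format_exc()

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "version": __version__,
        "started": t0,
        "elapsed_s": round(time.time() - t0, 3),
        "beta_xy_true": None if truth is None else truth.beta_xy_true,
    }
    return BatteryReport(sections=sections, errors=errors, provenance=provenance)


def write_report(report: BatteryReport, outdir: str | Path) -> list[Path]:
    """One CSV per section, a JSON summary, and a log file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in report.sections.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    summary = {
        "provenance": report.provenance,
        "sections": {name: json.loads(df.to_json(orient="records"))
                     for name, df in report.sections.items()},
        "errors": report.errors,
    }
    jpath = outdir / "report.json"
    jpath.write_text(json.dumps(summary, indent=1, default=str))
    written.append(jpath)
    lpath = outdir / "run.log"
    lpath.write_text(report.summary() + "\n")
    written.append(lpath)
    return written
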