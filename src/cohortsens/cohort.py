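"""Cohort table container: typed variables, causal roles, missing-value markers.

A :class:`CohortTable` is the single in-memory currency of the package. It
wraps a :class:`pandas.DataFrame` (missing entries as NaN) together with a
role map assigning each variable a causal role — exposure, outcome,
confounder, a variable that may be both confounder and mediator, or an
auxiliary used only by imputation models. Serialization is plain CSV
(empty cell = missing) with a JSON sidecar holding types and roles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["Role", "VarType", "Variable", "CohortTable", "SpecificationError"]


class SpecificationError(ValueError):
    """A cohort/model specification refers to undeclared variables or has
    invalid parameters; the message names the offending variable."""


class Role:
    EXPOSURE = "exposure"
    OUTCOME = "outcome"
    CONFOUNDER = "confounder"
    CONFOUNDER_OR_MEDIATOR = "confounder_or_mediator"
    AUXILIARY = "auxiliary"
    OTHER = "other"

    ALL = (EXPOSURE, OUTCOME, CONFOUNDER, CONFOUNDER_OR_MEDIATOR, AUXILIARY, OTHER)


class VarType:
    BINARY = "binary"
    CATEGORICAL = "categorical"
    CONTINUOUS = "continuous"

    ALL = (BINARY, CATEGORICAL, CONTINUOUS)


@dataclass(frozen=True)
class Variable:
    name: str
    vtype: str
    role: str

    def __post_init__(self):
        if self.vtype not in VarType.ALL:
            raise SpecificationError(f"unknown variable type {self.vtype!r} for {self.name!r}")
        if self.role not in Role.ALL:
            raise SpecificationError(f"unknown role {self.role!r} for {self.name!r}")


@dataclass
class CohortTable:
    """Rectangular cohort records plus the variable role map.

    Parameters
    ----------
    data
        One column per declared variable; missing entries are NaN
        (categorical columns use pandas ``object``/string values).
    variables
        Declared variables in column order. Exactly one exposure and one
        outcome are required, both binary.
    """

    data: pd.DataFrame
    variables: list[Variable] = field(default_factory=list)

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SpecificationError("duplicate variable names in role map")
        missing_cols = set(names) - set(self.data.columns)
        if missing_cols:
            raise SpecificationError(f"columns absent from data: {sorted(missing_cols)}")
        self.data = self.data.loc[:, names].reset_index(drop=True)
        if len([v for v in self.variables if v.role == Role.EXPOSURE]) != 1:
            raise SpecificationError("exactly one exposure variable required")
        if len([v for v in self.variables if v.role == Role.OUTCOME]) != 1:
            raise SpecificationError("exactly one outcome variable required")
        for v in self.variables:
            if v.vtype == VarType.BINARY:
                col = self.data[v.name]
                vals = col.dropna().unique()
                if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
                    raise SpecificationError(f"binary variable {v.name!r} has values outside {{0,1}}")

    # -- convenience accessors -------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def exposure(self) -> str:
        return next(v.name for v in self.variables if v.role == Role.EXPOSURE)

    @property
    def outcome(self) -> str:
        return next(v.name for v in self.variables if v.role == Role.OUTCOME)

    def var(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def names_with_role(self, *roles: str) -> list[str]:
        return [v.name for v in self.variables if v.role in roles]

    @property
    def confounders(self) -> list[str]:
        return self.names_with_role(Role.CONFOUNDER)

    @property
    def confounders_or_mediators(self) -> list[str]:
        return self.names_with_role(Role.CONFOUNDER_OR_MEDIATOR)

    @property
    def auxiliaries(self) -> list[str]:
        return self.names_with_role(Role.AUXILIARY)

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def missing_fraction(self) -> pd.Series:
        return self.data.isna().mean()

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), list(self.variables))

    # -- serialization ---------------------------------------------------
    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write records as CSV (empty cell = missing) and a JSON sidecar
        with the variable types and roles."""
        path = Path(path)
        self.data.to_csv(path, index=False, na_rep="")
        side = Path(sidecar) if sidecar is not None else path.with_suffix(".roles.json")
        payload = {
            "variables": [
                {"name": v.name, "type": v.vtype, "role": v.role} for v in self.variables
            ]
        }
        side.write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path | None = None) -> "CohortTable":
        path = Path(path)
        side = Path(sidecar) if sidecar is not None else path.with_suffix(".roles.json")
        meta = json.loads(side.read_text())
        variables = [Variable(d["name"], d["type"], d["role"]) for d in meta["variables"]]
        dtypes = {v.name: (object if v.vtype == VarType.CATEGORICAL else float) for v in variables}
        df = pd.read_csv(path, dtype=dtypes, keep_default_na=True)
        return cls(df, variables)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        roles: Mapping[str, str],
        types: Mapping[str, str] | None = None,
    ) -> "CohortTable":
        """Build a table from a DataFrame and a ``{name: role}`` map.

        Types are inferred when not given: object/categorical dtype →
        categorical, two unique values {0,1} → binary, else continuous.
        """
        variables = []
        for name in df.columns:
            if name not in roles:
                raise SpecificationError(f"no role declared for column {name!r}")
            if types and name in types:
                vtype = types[name]
            else:
                col = df[name]
                if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                    vtype = VarType.CATEGORICAL
                else:
                    vals = set(np.asarray(col.dropna().unique(), dtype=float))
                    vtype = VarType.BINARY if vals <= {0.0, 1.0} else VarType.CONTINUOUS
            variables.append(Variable(name, vtype, roles[name]))
        return cls(df.copy(), variables)
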