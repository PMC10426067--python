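import numpy as np
import pandas as pd
import pytest

from cohortsens.cohort import CohortTable, Role, Variable, VarType


def two_by_two_table(a: int, b: int, c: int, d: int) -> CohortTable:
    """Cohort from 2x2 counts: a=(x=1,y=1), b=(x=1,y=0), c=(x=0,y=1), d=(x=0,y=0)."""
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    df = pd.DataFrame({"x": x, "y": y})
    return CohortTable(df, [Variable("x", VarType.BINARY, Role.EXPOSURE),
                            Variable("y", VarType.BINARY, Role.OUTCOME)])


@pytest.fixture(scope="session")
def table_50_50_25_75() -> CohortTable:
    return two_by_two_table(50, 50, 25, 75)


@pytest.fixture(scope="session")
def small_cohort():
    """Small complete default cohort shared across tests (n=4000, seed 123)."""
    from cohortsens.synthdata import default_spec, generate

    spec = default_spec(n=4000)
    table, truth = generate(spec, 123)
    return spec, table, truth
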