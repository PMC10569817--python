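import numpy as np
import pandas as pd
import pytest

from cohortbalance import (
    Cohort,
    VariableSchema,
    default_vital_like_config,
    generate_cohort,
)


def make_cohort(records: dict, outcome: str = "event", provenance: str = "fixture") -> Cohort:
    """Build a small cohort from column dict, inferring a minimal schema."""
    df = pd.DataFrame(records)
    schema = []
    for col in df.columns:
        if df[col].dtype.kind in "if":
            schema.append(VariableSchema(col, "continuous"))
        else:
            levels = tuple(pd.unique(df[col].astype(str)))
            role = "outcome" if col == outcome else "predictor"
            if role == "outcome":
                # declared order is (non-event, event); "No" < "Yes" sorts right
                levels = tuple(sorted(levels))
                if len(levels) == 1:
                    levels = ("__other__",) + levels
            schema.append(VariableSchema(col, "categorical", levels, role))
            df[col] = df[col].astype(str)
    return Cohort(df, schema, provenance)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 4,000-row default-parameter synthetic cohort (seed 7)."""
    return generate_cohort(default_vital_like_config(seed=7, n=4000))


@pytest.fixture(scope="session")
def medium_synthetic():
    """A 12,000-row default-parameter synthetic cohort (seed 11)."""
    return generate_cohort(default_vital_like_config(seed=11, n=12000))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
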