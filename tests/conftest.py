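import numpy as np
import pandas as pd
import pytest

from metsrisk import CohortSpec, generate_cohort, risk_factor_table


@pytest.fixture(scope="session")
def cohort6k() -> pd.DataFrame:
    """Shared synthetic cohort (n=6,000, fixed seed) for model-level tests."""
    return generate_cohort(CohortSpec(n=6000, seed=11))


@pytest.fixture(scope="session")
def labels6k(cohort6k) -> pd.Series:
    rf = risk_factor_table(cohort6k)
    return pd.Series(
        rf["mets"].to_numpy(), index=cohort6k["id"].to_numpy(), name="mets"
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_record(**overrides) -> dict:
    """A healthy reference participant; override fields to flip risk factors."""
    rec = dict(
        id="P1",
        sex="M",
        age=50,
        height=170.0,
        weight=70.0,
        waist=80.0,
        hip=95.0,
        sbp=110.0,
        dbp=70.0,
        glucose=90.0,
        triglycerides=100.0,
        hdl=60.0,
    )
    rec.update(overrides)
    return rec
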