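import numpy as np
import pandas as pd
import pytest

from newborntypes import ToyWeightFamily


def make_records(rows):
    """Build a canonical record frame from per-record dicts with defaults."""
    defaults = {
        "country": "AA",
        "year": 2015,
        "ga_days": 280,
        "bw_grams": 3300,
        "sex": "female",
        "plurality": "singleton",
        "ga_week_resolution": False,
    }
    filled = [{**defaults, **row} for row in rows]
    df = pd.DataFrame(filled, columns=list(defaults))
    df["ga_days"] = df["ga_days"].astype("Int64")
    df["bw_grams"] = df["bw_grams"].astype("Int64")
    df["sex"] = df["sex"].astype(object).where(pd.notna(df["sex"]), np.nan)
    return df


@pytest.fixture
def rec():
    return make_records


@pytest.fixture(scope="session")
def toy_family():
    return ToyWeightFamily()


@pytest.fixture(scope="session")
def toy_standard(toy_family):
    return toy_family.standard()


@pytest.fixture(scope="session")
def flat_family():
    """Gaussian family with constant mean 3000 g / SD 400 g at all ages."""
    knots = tuple(range(154, 309, 7)) + (314,)
    return ToyWeightFamily(
        knot_days=knots,
        mean_female=(3000.0,) * len(knots),
        male_offset_g=0.0,
        sd_constant_g=400.0,
    )


@pytest.fixture(scope="session")
def flat_standard(flat_family):
    return flat_family.standard()
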