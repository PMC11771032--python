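import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_life_table():
    from guhapaths.lifetable import LifeTable

    entries = {}
    for age in range(44, 59):
        entries[("female", age)] = 33.0 - 0.8 * (age - 44)
        entries[("male", age)] = 27.0 - 0.8 * (age - 44)
    return LifeTable(entries)


@pytest.fixture
def tiny_cohort():
    """Six participants covering died/alive, both sexes, fractional ages."""
    return pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(6)],
            "sex": ["female", "male", "female", "male", "female", "male"],
            "age": [50.7, 44.0, 58.2, 52.5, 47.1, 55.9],
            "vital_status": [
                "died", "died", "alive_at_censor", "died", "alive_at_censor", "died",
            ],
            "years_survived": [20.0, 26.0, 29.0, 10.0, 29.0, 18.5],
            "bmi": [26.0, 19.5, np.nan, 31.2, 22.0, 24.9],
        }
    )


@pytest.fixture
def bmi_coding():
    from guhapaths.coding import AttributeCoding, Predicate

    return AttributeCoding(
        attribute="bmi",
        predicates=(
            Predicate(label="<20", interval=(None, 20.0)),
            Predicate(label="20-<25", interval=(20.0, 25.0)),
            Predicate(label="25-<30", interval=(25.0, 30.0)),
            Predicate(label="30-", interval=(30.0, None)),
        ),
    )


@pytest.fixture
def sex_coding():
    from guhapaths.coding import AttributeCoding, Predicate

    return AttributeCoding(
        attribute="sex",
        predicates=(
            Predicate(label="male", categories=frozenset({"male"})),
            Predicate(label="female", categories=frozenset({"female"})),
        ),
    )
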