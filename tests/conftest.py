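import pandas as pd
import pytest

from ipwet import CohortConfig, builtin_tape, generate_cohort


@pytest.fixture(scope="session")
def broselow():
    return builtin_tape("broselow_2007b")


@pytest.fixture(scope="session")
def ipwet_tape():
    return builtin_tape("ipwet")


@pytest.fixture(scope="session")
def study_cohort():
    """Derivation-sized cohort at the default (study) parametrization."""
    return generate_cohort(CohortConfig(n=769, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for moment/property checks."""
    return generate_cohort(CohortConfig(n=10_000, seed=7))


def make_cohort(heights, weights, sexes=None, ages=None) -> pd.DataFrame:
    """Hand-built cohort frame for oracle tests."""
    n = len(heights)
    return pd.DataFrame(
        {
            "child_id": [f"K{i:03d}" for i in range(n)],
            "age_months": ages if ages is not None else [24.0] * n,
            "sex": sexes if sexes is not None else ["M"] * n,
            "height_cm": list(heights),
            "weight_kg": list(weights),
        }
    )
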