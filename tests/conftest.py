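import numpy as np
import pandas as pd
import pytest

from antithrombo.ehr_core import StudyConfig
from antithrombo.synthetic_ehr import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def study() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def small_cohort(study):
    """A 600-patient synthetic cohort shared across integration tests."""
    return generate_cohort(GeneratorConfig(n_patients=600, seed=11), study)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_issue_stream(rng: np.random.Generator, max_issues: int = 15) -> list[int]:
    """A random prescription stream (day offsets, first at 0)."""
    n = int(rng.integers(1, max_issues + 1))
    gaps = rng.integers(1, 120, size=n - 1)
    return [0] + list(np.cumsum(gaps))


def dated(day: int, origin: str = "2010-01-01") -> pd.Timestamp:
    return pd.Timestamp(origin) + pd.Timedelta(days=day)
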