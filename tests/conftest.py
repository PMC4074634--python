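from pathlib import Path

import pytest

from claimprev import SimulationConfig, StudyWindow, generate_claims

REPO_ROOT = Path(__file__).resolve().parents[1]
DEMO_CONFIG = REPO_ROOT / "examples" / "demo_config.json"


@pytest.fixture(scope="session")
def window() -> StudyWindow:
    return StudyWindow(2004, 2005, 2006)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A down-scaled cohort in multinomial (weights) mode for fast tests."""
    return SimulationConfig(
        n_patients=800,
        count_mode="weights",
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(claims, truth) for the down-scaled cohort."""
    return generate_claims(small_config)


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    """The study-conditions extract: fixed group counts, group PPVs."""
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def study_cohort(study_config):
    return generate_claims(study_config)
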