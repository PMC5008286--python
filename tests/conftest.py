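import pandas as pd
import pytest

from imprintscore.scoring import score_cohort
from imprintscore.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def study_config() -> SimulationConfig:
    """Study-sized cohort (8 normal / 23 early / 9 late)."""
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def calibration_config() -> SimulationConfig:
    """Large cohort for parameter-recovery checks."""
    return SimulationConfig(n_per_group=1000, seed=7)


@pytest.fixture(scope="session")
def calibration_cohort(calibration_config) -> pd.DataFrame:
    return simulate_cohort(calibration_config)


@pytest.fixture(scope="session")
def calibration_scores(calibration_cohort) -> pd.DataFrame:
    return score_cohort(calibration_cohort)


@pytest.fixture(scope="session")
def study_cohort(study_config) -> pd.DataFrame:
    return simulate_cohort(study_config)
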