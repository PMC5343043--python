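import warnings

import numpy as np
import pytest

from cortmed.config import SimulationConfig, paper_calibrated
from cortmed.mediation import build_analysis_frame
from cortmed.simulate import generate_cohort
from cortmed.trajectory import TrajectorySpec

# arviz announces its refactor on import; irrelevant here
warnings.filterwarnings("ignore", message=".*ArviZ is undergoing a major refactor.*")


@pytest.fixture(scope="session")
def default_cfg():
    return paper_calibrated()


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """One default-profile cohort of n=117."""
    return generate_cohort(default_cfg, np.random.default_rng(2024))


@pytest.fixture(scope="session")
def analysis_frame(cohort):
    subjects, biomarkers = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frame, log = build_analysis_frame(subjects, biomarkers, TrajectorySpec(seed=7))
    return frame, log


def cfg_with(base: SimulationConfig, **kw) -> SimulationConfig:
    return SimulationConfig(**{**base.to_dict(), **kw})
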