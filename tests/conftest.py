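import numpy as np
import pytest

from peatsense.pipeline import run_analysis
from peatsense.synthetic_data import StudyConfig, generate_study


@pytest.fixture(scope="session")
def study_dataset():
    """One default synthetic campaign, shared across read-only tests."""
    return generate_study(StudyConfig(seed=7))


@pytest.fixture(scope="session")
def study_report(study_dataset):
    return run_analysis(dataset=study_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
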