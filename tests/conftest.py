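import numpy as np
import pytest

from wmd.config import PipelineConfig
from wmd.pipeline import extract_feature_table
from wmd.synth import generate_dataset


@pytest.fixture(scope="session")
def study_dataset():
    """The full synthetic study: 4 classes x 12 reps x 7.5 s plus background."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def study_features(study_dataset):
    """Default-config feature table for the study dataset (one row per window)."""
    return extract_feature_table(study_dataset, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
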