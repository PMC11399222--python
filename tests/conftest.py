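import numpy as np
import pytest

from carpalkit.pipeline import PipelineConfig, train_models
from carpalkit.synthetic import generate_cohort


@pytest.fixture(scope="session")
def train_cohort():
    """Normal training cohort (includes widened-but-aligned wrists so
    pure arc lengthening is inside the normal shape space)."""
    return generate_cohort(30, seed=11, spacing_mm_per_px=0.2,
                           widened_frac=0.25)


@pytest.fixture(scope="session")
def registry(train_cohort):
    """Bone PDMs + arc interruption detector trained on the fixture cohort."""
    return train_models(train_cohort, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
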