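import numpy as np
import pytest

from gaitdrift import (
    GeneratorConfig,
    build_feature_matrix,
    default_schedule,
    generate_dataset,
)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def grf_matrix():
    """One subject's fully preprocessed 90 x 600 GRF matrix (default drift)."""
    trials = generate_dataset(GeneratorConfig(n_subjects=1, seed=42))
    return build_feature_matrix(trials, "grf")


@pytest.fixture(scope="session")
def angles_matrix():
    """One subject's fully preprocessed 90 x 1800 joint-angle matrix."""
    trials = generate_dataset(
        GeneratorConfig(n_subjects=1, modality="angles", seed=42)
    )
    return build_feature_matrix(trials, "angles")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
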