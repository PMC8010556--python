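import numpy as np
import pytest

from qibrepeat import StudyConfig, VarianceComponents, default_study_config
from qibrepeat.config import LESION_CLASSES, METRICS
from qibrepeat.synthetic import generate_measurement_table


def uniform_config(
    n_subjects: int = 5,
    mean: float = 100.0,
    between: float = 0.0,
    intra: float = 0.0,
    inter: float = 0.0,
    seed: int = 0,
) -> StudyConfig:
    """Study config with identical variance components in every cell."""
    components = {
        (metric, cls): VarianceComponents(
            true_group_mean=mean,
            between_subject_sd=between,
            intra_reader_sw=intra,
            inter_reader_sw=inter,
        )
        for metric in METRICS
        for cls in LESION_CLASSES
    }
    return StudyConfig(n_subjects=n_subjects, components=components, seed=seed)


@pytest.fixture(scope="session")
def reference_config():
    """Default 22-subject config calibrated to the reference study grid."""
    return default_study_config(seed=1234)


@pytest.fixture(scope="session")
def reference_table(reference_config):
    return generate_measurement_table(reference_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
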