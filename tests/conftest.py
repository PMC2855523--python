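import numpy as np
import pytest

from mirtlda.normalization import normalize
from mirtlda.synthetic_data import (
    generate_dataset,
    study_like_preset,
    two_group_preset,
)


@pytest.fixture(scope="session")
def study_dataset():
    """One study-like synthetic dataset (26 samples, 666 assays, 30
    planted effects on the older-adult melanoma group)."""
    return generate_dataset(study_like_preset(seed=11))


@pytest.fixture(scope="session")
def study_norm(study_dataset):
    ctm, _, _ = study_dataset
    return normalize(ctm)


@pytest.fixture(scope="session")
def two_group_dataset():
    """Balanced 10 vs 10 design with 30 planted 4-fold effects."""
    return generate_dataset(two_group_preset(seed=11))


def group_labels(annotations):
    return np.array([a.group for a in annotations], dtype=object)
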