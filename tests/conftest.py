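import numpy as np
import pytest

from ecgfusion.preprocess import SegmentationConfig
from ecgfusion.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_dataset():
    """2000 imbalanced synthetic beats at desk scale (seq 50, 28x28 images).

    Session-scoped: shared between the protocol tests and the learning
    acceptance test so the CWT pipeline runs once.
    """
    return generate_dataset(
        SyntheticConfig(n_beats=2000, seed=7),
        seg_cfg=SegmentationConfig(target_len=50),
        image_shape=(28, 28),
    )


@pytest.fixture(scope="session")
def separable_dataset():
    """Clean, balanced beats that a classifier should nail (low jitter,
    no noise): the oracle for cross-validation on separable data."""
    return generate_dataset(
        SyntheticConfig(n_beats=64, seed=5, noise_sd=0.0, baseline_amp=0.05,
                        amplitude_jitter=0.02,
                        class_proportions=(0.25, 0.25, 0.25, 0.25)),
        seg_cfg=SegmentationConfig(target_len=50),
        image_shape=(28, 28),
        n_scales=50,
    )


@pytest.fixture(scope="session")
def micro_dataset():
    """A tiny balanced-ish dataset for fast protocol/driver tests."""
    return generate_dataset(
        SyntheticConfig(n_beats=80, class_proportions=(0.4, 0.2, 0.3, 0.1),
                        seed=3),
        seg_cfg=SegmentationConfig(target_len=20),
        image_shape=(12, 12),
        n_scales=20,
    )
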