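import numpy as np
import pytest

from vfssvit import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small noisy study shared by read-only tests."""
    cfg = SyntheticConfig(
        n_subjects=4, clips_per_subject=2, frame_hw=(48, 48),
        length_range=(20, 30), seed=7,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def clean_study():
    """Noise-free study: the planted signal is exact, not statistical."""
    cfg = SyntheticConfig(
        n_subjects=5, clips_per_subject=2, frame_hw=(48, 48),
        length_range=(18, 24), noise_sigma=0.0, seed=3,
    )
    return generate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
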