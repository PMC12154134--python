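import numpy as np
import pytest

from ipmnrisk import CenterProfile, SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def quiet_profile():
    """Acquisition profile with no bias, no noise, unit scale."""
    return CenterProfile(slice_thickness=4.0, bias_amplitude=0.0, noise_sd=0.0,
                         intensity_scale=1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 30-subject, 3-center cohort with a strong class effect."""
    cfg = SynthConfig(
        n_subjects=30,
        n_centers=3,
        class_balance=0.4,
        effect_size=2.0,
        volume_shape=(24, 24, 16),
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
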