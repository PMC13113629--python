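import numpy as np
import pytest

from petmr_hybrid import SyntheticConfig, generate_cohort
from petmr_hybrid.volumes import DceSeries, ImageVolume, LesionMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (n=159), shared across tests."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture
def noiseless_config():
    return SyntheticConfig(seed=5, pet_noise_sd_scale=0.0, mr_rician_sigma=0.0)


def make_volume(data, modality="PET_SUV"):
    return ImageVolume(np.asarray(data, dtype=float), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), modality)


def make_series(phase_values, shape=(4, 4, 4)):
    """Constant-valued six-phase series."""
    return DceSeries([make_volume(np.full(shape, v), "DCE_SI") for v in phase_values])


@pytest.fixture
def ball_mask():
    data = np.zeros((8, 8, 8), dtype=bool)
    data[3:6, 3:6, 3:6] = True
    return LesionMask(data, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), "truth")
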