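import numpy as np
import pytest

from petmr_concordance import SyntheticLesionSpec, make_lesion_pair


@pytest.fixture(scope="session")
def noisefree_pair_offset20():
    """Noise-free phantom with a 20 mm inter-focus offset."""
    spec = SyntheticLesionSpec(
        semi_axes=(30.0, 24.0, 21.0),
        suv_focus=(10.0, 0.0, 0.0),
        adc_trough=(-10.0, 0.0, 0.0),
        noise_sd_suv=0.0,
        noise_sd_adc=0.0,
        noise_sd_dwi=0.0,
        rim_outlier_fraction=0.0,
        seed=7,
    )
    return make_lesion_pair(spec)


@pytest.fixture(scope="session")
def noisefree_pair_coincident():
    """Noise-free phantom with coincident SUV and ADC foci."""
    spec = SyntheticLesionSpec(
        semi_axes=(28.0, 22.0, 18.0),
        noise_sd_suv=0.0,
        noise_sd_adc=0.0,
        noise_sd_dwi=0.0,
        rim_outlier_fraction=0.0,
        seed=11,
    )
    return make_lesion_pair(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
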