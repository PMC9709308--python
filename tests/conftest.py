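import numpy as np
import pytest

from binloc.features import FeatureConfig
from binloc.synthetic import HeadModel, SceneConfig, generate_dataset


@pytest.fixture(scope="session")
def desk_cfg():
    """Reduced-resolution analysis (K=128 at 16 kHz, D=90) used desk-scale."""
    return FeatureConfig(dft_size=128)


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def clean_coarse_ds():
    """Clean (noise-free, anechoic) coarse grid: 19 x 7 directions."""
    scene = SceneConfig(azimuths_deg=tuple(range(-90, 91, 10)),
                        elevations_deg=tuple(range(-45, 46, 15)),
                        snr_db=np.inf, reverb_strength=0.0)
    return generate_dataset(scene)


@pytest.fixture(scope="session")
def reverb_coarse_ds():
    """Noisy reverberant coarse grid (15 dB SNR, reverb 0.5), 2 repeats."""
    scene = SceneConfig(azimuths_deg=tuple(range(-90, 91, 10)),
                        elevations_deg=tuple(range(-45, 46, 15)),
                        repeats=2, snr_db=15.0, reverb_strength=0.5)
    return generate_dataset(scene)
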