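import numpy as np
import pytest

from laryngoscreen import Modality, SynthConfig, generate_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """Small frames for fast unit tests."""
    return SynthConfig(seed=7, image_size=(64, 64), lesion_area_range=(300, 900),
                       distractor_area_range=(5, 30))


@pytest.fixture(scope="session")
def cancer_frame(small_cfg):
    return generate_frame(small_cfg, cancer=True, modality=Modality.WLI)


@pytest.fixture(scope="session")
def benign_frame(small_cfg):
    return generate_frame(small_cfg, cancer=False, modality=Modality.NBI)
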