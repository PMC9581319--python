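import numpy as np
import pytest

from xylograft import synthetic_data as sd


@pytest.fixture(scope="session")
def clean_section() -> sd.SectionGroundTruth:
    """Noise-free rendered section with ground truth (seed fixed)."""
    return sd.render_xylem_section(sd.preset_section_spec("glera_like", seed=11))


@pytest.fixture(scope="session")
def noisy_section() -> sd.SectionGroundTruth:
    """Same scene family with additive Gaussian noise at 10% of the 8-bit
    dynamic range."""
    return sd.render_xylem_section(
        sd.preset_section_spec("glera_like", seed=11, noise_sigma=25.5)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
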