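import numpy as np
import pytest

from fluoragg import PipelineConfig, high_snr_scene
from fluoragg.pipeline import denoise_image
from fluoragg.imgio import extract_green
from fluoragg.synthetic import apply_noise, generate_scene


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def disk_fixture():
    """Distractor-free 10-disk scene with realistic noise (seed-pinned)."""
    scene = generate_scene(
        n_particles=10,
        radius_range=(6, 9),
        particle_shape="disk",
        n_distractors=0,
        seed=5,
    )
    return apply_noise(scene, gaussian_sigma=6.0, poisson=True, seed=6)


@pytest.fixture(scope="session")
def denoised_disk_fixture(disk_fixture, default_config):
    """Green channel of the disk fixture after the full denoising chain."""
    return denoise_image(extract_green(disk_fixture.image), default_config)


@pytest.fixture(scope="session")
def high_snr_fixture():
    return high_snr_scene(seed=1, n_particles=10)


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
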