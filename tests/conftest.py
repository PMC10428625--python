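import numpy as np
import pytest

from cropseg.synthetic_data import SceneParams, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """64×64 noisy scene with all three crops present."""
    return generate_scene(
        SceneParams(height=64, width=64, n_plots=12, signature_sd=0.02, seed=3)
    )


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free 64×64 scene: every pixel equals its class signature."""
    return generate_scene(
        SceneParams(
            height=64, width=64, n_plots=12, signature_sd=0.0,
            background_fraction=0.0, seed=3,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
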