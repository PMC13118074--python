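import numpy as np
import pytest

from hsiseg.calib import median_filter_bands
from hsiseg.phantom import (PhantomConfig, make_phantom_scene,
                            render_illumination_set)
from hsiseg.spectra import default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, shading-free, glare-free scene: reflectance == R_vol."""
    config = PhantomConfig(height=140, width=260, n_fruits=4, fruit_radius=22,
                           noise_sd=0.0, shading="none", lobe_amplitude=0.0,
                           seed=11)
    truth = make_phantom_scene(config)
    ill = render_illumination_set(truth, noise_sd=0.0)
    return truth, ill


@pytest.fixture(scope="session")
def glare_scene():
    """Noiseless scene with specular lobes but no shading."""
    config = PhantomConfig(height=140, width=260, n_fruits=4, fruit_radius=22,
                           noise_sd=0.0, shading="none", seed=7)
    truth = make_phantom_scene(config)
    ill = render_illumination_set(truth, noise_sd=0.0)
    return truth, ill


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-physics scene: shading, glare and 1% multiplicative noise."""
    config = PhantomConfig(height=160, width=300, n_fruits=6, fruit_radius=22,
                           noise_sd=0.01, seed=3)
    truth = make_phantom_scene(config)
    ill = render_illumination_set(truth)
    ill.obj = [median_filter_bands(c) for c in ill.obj]
    ill.ref = [median_filter_bands(c) for c in ill.ref]
    return truth, ill


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
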