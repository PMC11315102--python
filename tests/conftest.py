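import numpy as np
import pytest

import progseg as ps
from progseg.model import ModelConfig


@pytest.fixture(scope="session")
def phantom32():
    """A 3-organ 32^3 phantom with its smooth DVF (session-cached)."""
    cfg = ps.PhantomConfig(shape=(32, 32, 32), n_structures=3, seed=7)
    img, contours = ps.make_phantom(cfg)
    dvf = ps.make_smooth_dvf(cfg.shape, cfg.dvf_amplitude, cfg.dvf_smoothness, seed=11)
    return img, contours, dvf


@pytest.fixture(scope="session")
def series32(phantom32):
    img, contours, dvf = phantom32
    return ps.simulate_fractions(img, contours, dvf, scales=(-1.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest model that still exercises pooling, skips and the LSTM."""
    return ModelConfig(in_channels=3, out_channels=2, base_features=2,
                       levels=2, variant="lstm_unet", seed=3)


@pytest.fixture(scope="session")
def tiny_series():
    """An 8^3 two-structure course for fast end-to-end loops."""
    cfg = ps.PhantomConfig(shape=(8, 8, 8), n_structures=1, noise_sd=0.01,
                           dvf_amplitude=1.0, dvf_smoothness=2.0, seed=5)
    img, contours = ps.make_phantom(cfg)
    extra = np.zeros(cfg.shape, dtype=np.uint8)
    extra[1:3, 1:3, 1:3] = 1
    contours = ps.StructureSet({**contours.masks, "organ_2": extra})
    dvf = ps.make_smooth_dvf(cfg.shape, 1.0, 2.0, seed=6)
    return ps.simulate_fractions(img, contours, dvf, scales=(-1.0, 0.0, 1.0))


def rand_rng(seed=0):
    return np.random.default_rng(seed)
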