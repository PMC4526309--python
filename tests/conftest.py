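import numpy as np
import pytest

from texnac import DynamicSeries, PhantomConfig, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_curve_series():
    """A 4-pixel uniform series realizing the worked enhancement curve
    [0, 50, 80, 70, 65, 60] at 60 s spacing."""
    signal = np.array([0.0, 50.0, 80.0, 70.0, 65.0, 60.0])
    frames = 100.0 + np.tile(signal[:, None, None], (1, 2, 2))
    return DynamicSeries(frames, np.arange(6) * 60.0)


@pytest.fixture
def clean_phantom():
    """Noise-free, texture-free phantom: uniform 80 AU lesion peaking at frame 2."""
    cfg = PhantomConfig(noise_sd=0.0, lesion_texture_corr_len=0.0,
                        lesion_kinetics=(80.0, 0.8, -0.05), fat_fraction=0.0)
    series, truth = generate_phantom(cfg)
    return cfg, series, truth


def random_masked_image(rng, min_side=8, max_side=16, n_levels=8, p_mask=0.75):
    """A random quantized image with a random (connected-enough) mask."""
    h = int(rng.integers(min_side, max_side + 1))
    w = int(rng.integers(min_side, max_side + 1))
    levels = rng.integers(0, n_levels, size=(h, w))
    mask = rng.random((h, w)) < p_mask
    if not mask.any():
        mask[h // 2, w // 2] = True
    return levels, mask
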