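import numpy as np
import pytest

from acqua.synth import SceneConfig, generate_scene, render


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_scene():
    """One clean synthetic scene (no breaks, blobs or crossings) with truth."""
    cfg = SceneConfig(seed=7, n_filaments=6)
    truth = generate_scene(cfg)
    return truth, render(truth, cfg)


def straight_bar(height=4, width=200, pad=10):
    """Solid horizontal bar mask, padded with background."""
    m = np.zeros((height + 2 * pad, width + 2 * pad), dtype=bool)
    m[pad:pad + height, pad:pad + width] = True
    return m


def x_cross(n=61, thickness=1):
    """X-shaped mask from two crossing diagonals (1 px by default)."""
    m = np.zeros((n, n), dtype=bool)
    idx = np.arange(n)
    for t in range(thickness):
        m[np.clip(idx + t, 0, n - 1), idx] = True
        m[np.clip(n - 1 - idx + t, 0, n - 1), idx] = True
    return m
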