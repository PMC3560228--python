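import numpy as np
import pytest

from microcirc.io import VideoSequence
from microcirc.phantom import PhantomSpec, render_sequence, scaled_spec


@pytest.fixture(scope="session")
def small_phantom():
    """A small seeded baseline phantom with ground truth (shared)."""
    spec = scaled_spec(160, 224, seed=5)
    video, gt = render_sequence(spec)
    return spec, video, gt


@pytest.fixture()
def toy_band():
    """The 9x9 toy grid: bright background 0.8, vertical band cols 3-5
    at 0.4 (a width-3 dark vessel)."""
    img = np.full((9, 9), 0.8)
    img[:, 3:6] = 0.4
    return img


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def textured_frames(n_frames=6, shape=(96, 128), seed=0, smooth=2.0):
    """Static textured scene repeated n times (for I/O round trips)."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.random(shape), smooth)
    base = (base - base.min()) / (base.max() - base.min())
    return VideoSequence(np.repeat(base[None], n_frames, axis=0))
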