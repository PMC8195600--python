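import numpy as np
import pytest

from adipoquant import synth


@pytest.fixture(scope="session")
def clean_fish():
    """Noiseless, unblurred reporter image: planted masks are pixel-exact."""
    params = synth.ImageSimParams(noise_sd=0, blur_sigma=0, seed=11)
    img, truth = synth.generate_fish_image(params)
    return img, truth, params


@pytest.fixture(scope="session")
def default_fish():
    """Reporter image at default noise and edge blur."""
    img, truth = synth.generate_fish_image(synth.ImageSimParams(seed=5))
    return img, truth


@pytest.fixture(scope="session")
def sixteen_plate_screen():
    """Null screen (no inhibitors) with edge bias, noiseless."""
    params = synth.ScreenSimParams(position_bias=synth.edge_bias_grid(), cv=0.0, seed=2)
    plates, truth = synth.generate_screen(params)
    return plates, truth, params


def disc_lattice_count(radius: float) -> int:
    """Independent oracle: lattice points with x^2 + y^2 <= r^2."""
    r = int(np.ceil(radius))
    xs = np.arange(-r, r + 1)
    xx, yy = np.meshgrid(xs, xs)
    return int(np.sum(xx**2 + yy**2 <= radius**2))
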