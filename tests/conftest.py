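import numpy as np
import pytest

from pasquant import synthetic
from pasquant.images import correct_background, rgb_to_hsb


@pytest.fixture(scope="session")
def noisefree_flat_render():
    """Noise-free, flat-light scene spanning the p_pas range; the cleanest
    conditions for end-to-end index recovery."""
    scene = synthetic.make_grid_scene(
        [0.0, 0.05, 0.2, 0.35, 0.5, 0.65, 0.8, 1.0],
        noise_sd=0.0,
        flat_illumination=True,
        seed=42,
    )
    return synthetic.render_scene(scene)


@pytest.fixture(scope="session")
def vignetted_render():
    """Default-noise scene under the polynomial illumination field."""
    scene = synthetic.make_grid_scene(
        [0.05, 0.2, 0.35, 0.5, 0.65, 0.8],
        seed=43,
    )
    return synthetic.render_scene(scene)


@pytest.fixture(scope="session")
def noisefree_flat_hsb(noisefree_flat_render):
    r = noisefree_flat_render
    return rgb_to_hsb(correct_background(r.specimen, r.calibration))


@pytest.fixture(scope="session")
def expression_default():
    spec = synthetic.ExpressionSimSpec(seed=7)
    matrix, ann = synthetic.simulate_expression_matrix(spec)
    return spec, matrix, ann
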