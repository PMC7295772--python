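import numpy as np
import pytest

from ultrametric.synthetic import SceneSpec, render_micrograph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """A compact scene used across detection tests."""
    return SceneSpec(shape_px=(768, 768), seed=7)


@pytest.fixture
def rendered_three(small_scene):
    """Three well-separated oocytes of known diameter with ground truth."""
    rng = np.random.default_rng(7)
    micro, truth, leftover = render_micrograph(
        [300.0, 500.0, 900.0], small_scene, rng
    )
    assert leftover.size == 0
    return micro, truth
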