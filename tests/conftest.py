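import numpy as np
import pytest

from zctexture import segmentation
from zctexture.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default punctate scene with all confounds on."""
    return generate_scene(SceneConfig(seed=11))


@pytest.fixture(scope="session")
def default_cell(default_scene):
    return segmentation.make_cell_mask(default_scene.channels["ddr1"])


@pytest.fixture(scope="session")
def default_patch(default_scene, default_cell):
    patches = segmentation.segment_texture_patches(default_scene.channels["ddr1"], default_cell)
    return patches[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
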