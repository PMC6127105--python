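import numpy as np
import pytest

from hsbcyto import MultiChannelImage
from hsbcyto.synthetic import SceneSpec, generate_scene


def make_image(data, axes="CZYX", **kw):
    """Convenience: build a MultiChannelImage from a small array."""
    from hsbcyto.image import promote_axes

    data = np.asarray(data)
    return MultiChannelImage(data=promote_axes(data, axes), **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def three_pop_scene():
    """Noise-free scene: single-, double- and triple-positive cells."""
    spec = SceneSpec(
        shape_zyx=(20, 140, 140),
        n_cells={"R": 3, "G": 3, "B": 3, "RG": 2, "RGB": 2},
        seed=11,
    )
    img, truth = generate_scene(spec)
    return spec, img, truth
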