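import warnings

import pytest

from phenoprofiler.features import profile_image
from phenoprofiler.synthetic import SceneSpec, default_channel_map, render_scene


@pytest.fixture(scope="session")
def channel_map():
    return default_channel_map()


@pytest.fixture(scope="session")
def small_scene():
    """One mixed scene: interphase + mitotic cells, 40% ciliated."""
    spec = SceneSpec(
        n_cells=12, shape=(512, 512), seed=1, ciliated_prob=0.4, p_mitotic=0.3
    )
    return (*render_scene(spec), spec)


@pytest.fixture(scope="session")
def small_profile(small_scene, channel_map):
    image, mask, truth, _ = small_scene
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = profile_image(image, mask, channel_map, condition="ctrl")
    return table, truth
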