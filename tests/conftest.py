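import numpy as np
import pytest

from radixweed.geometry import PlanarPoint
from radixweed.pso import Scene
from radixweed.synth import ImageSceneConfig, gen_field_image, reference_scene


@pytest.fixture(scope="session")
def ref_scene() -> Scene:
    """The benchmark planning scene in plane-N coordinates."""
    s3, e3, obs, params = reference_scene()
    return Scene(
        s=PlanarPoint(0.0, 0.0),
        e=PlanarPoint(e3.x - s3.x, 0.0),
        obstacle=obs,
        params=params,
    )


@pytest.fixture(scope="session")
def small_field():
    """A small ground-truthed field image for fast unit tests."""
    cfg = ImageSceneConfig(height=400, width=400, n_weeds=8, n_crops=2, seed=11)
    img, truth = gen_field_image(cfg)
    return img, truth


def soil_image(h=60, w=60, color=(120, 90, 60)):
    return np.tile(np.array(color, dtype=np.uint8), (h, w, 1))
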