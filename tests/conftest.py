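import numpy as np
import pytest

from agesal.gaze_data import FixationRecord, FixationTable, SaliencyMap
from agesal.itti_saliency import ConspicuityStack
from agesal.synthetic_cohort import make_layered_scene


def make_table(points, dims=(64, 64), group="g", image_id="im",
               observer="ob"):
    """FixationTable from a list of (x, y) pairs; dims is (width, height)."""
    recs = [
        FixationRecord(observer_id=observer, group=group, image_id=image_id,
                       x=float(x), y=float(y))
        for x, y in points
    ]
    return FixationTable(records=recs, image_dims={image_id: dims})


@pytest.fixture
def random_map():
    def _make(seed=0, shape=(32, 32)):
        rng = np.random.default_rng(seed)
        g = rng.random(shape)
        g = (g - g.min()) / (g.max() - g.min())
        return SaliencyMap(grid=g, normalization="minmax01")
    return _make


@pytest.fixture(scope="session")
def layered_scene():
    return make_layered_scene((256, 256), 3, 8, seed=7)


@pytest.fixture(scope="session")
def layered_stack(layered_scene):
    return ConspicuityStack.from_image(layered_scene[0])
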