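import numpy as np
import pytest

from mousecbct.phantom import TumorSpec, make_mouse_phantom
from mousecbct.pipeline import SegmentationConfig, segment_mouse


@pytest.fixture(scope="session")
def tumor_phantom_50():
    """Single mouse, 50 mm^3 cheek tumor, default noise, 0.4 mm voxels."""
    return make_mouse_phantom(seed=2, tumor=TumorSpec.from_volume(50.0))


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Single tumor-free mouse (exactly mirror-symmetric head)."""
    return make_mouse_phantom(seed=3)


@pytest.fixture(scope="session")
def tumor_result_50(tumor_phantom_50):
    """Full segmentation of the 50 mm^3 tumor phantom."""
    vol, truth = tumor_phantom_50
    return segment_mouse(vol, SegmentationConfig()), truth


def rigid_rotate_z(coords, deg, center):
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    d = coords - center
    out = d.copy()
    out[:, 0] = c * d[:, 0] - s * d[:, 1]
    out[:, 1] = s * d[:, 0] + c * d[:, 1]
    return out + center
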