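import numpy as np
import pytest

from vasctree import phantoms
from vasctree.volume import TricubicSampler, Volume


@pytest.fixture(scope="session")
def small_torus():
    """Torus phantom in a compact volume (D=4, R1=12)."""
    vol, gt = phantoms.make_torus(4.0, 12.0, size=40.0, spacing=0.6)
    return vol, gt


@pytest.fixture(scope="session")
def cylinder_volume():
    """Straight z-aligned tube, radius 2 mm, in a compact volume."""
    size, spacing = 30.0, 0.6
    vol = phantoms.blank_volume(size, spacing)
    center = (np.array(vol.shape) - 1) * vol.spacing / 2.0
    axis_xy = center[:2]
    zs = np.arange(2.0, size - 2.0, 0.25 * spacing)
    pts = np.column_stack([np.full_like(zs, axis_xy[0]),
                           np.full_like(zs, axis_xy[1]), zs])
    phantoms.paint_curve(vol, pts, R=2.0)
    return vol, np.array([axis_xy[0], axis_xy[1]]), (zs[0], zs[-1])


@pytest.fixture(scope="session")
def cylinder_sampler(cylinder_volume):
    vol, _, _ = cylinder_volume
    return TricubicSampler(vol)
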