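import numpy as np
import pytest

from epics3d.reconstruct import ChromatinDomain
from epics3d.stack_io import DARK_IS_SIGNAL


def make_domain(coords, intensities=None, spacing=1.0, polarity=DARK_IS_SIGNAL,
                stack_id="s", batch_id="b", domain_id=1):
    coords = np.asarray(coords)
    if intensities is None:
        intensities = np.ones(len(coords))
    return ChromatinDomain(
        domain_id=domain_id,
        stack_id=stack_id,
        batch_id=batch_id,
        voxel_coords=coords,
        intensities=np.asarray(intensities, dtype=float),
        voxel_size_iso=spacing,
        polarity=polarity,
    )


def digital_ball(radius, spacing=1.0, **kw):
    r = int(np.ceil(radius))
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    mask = zz**2 + yy**2 + xx**2 <= radius**2
    coords = np.stack([zz[mask], yy[mask], xx[mask]], axis=1) + r
    return make_domain(coords, spacing=spacing, **kw)


def solid_cube(side, spacing=1.0, **kw):
    coords = np.argwhere(np.ones((side, side, side), dtype=bool))
    return make_domain(coords, spacing=spacing, **kw)


@pytest.fixture
def ball10():
    return digital_ball(10)


@pytest.fixture
def cube15():
    return solid_cube(15)
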