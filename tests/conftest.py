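import numpy as np
import pytest

from astroca.dynamics import ParameterSet
from astroca.morphology import (
    encode_template,
    generate_synthetic_astrocyte,
    intensity_to_avf,
)


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def small_cell_template():
    """Compact synthetic astrocyte on the network grid step (fast to integrate)."""
    img = generate_synthetic_astrocyte(
        extent=22.0, pixel_size=0.55, soma_radius=3.0,
        n_primary_branches=4, seed=11,
    )
    return encode_template(intensity_to_avf(img))


@pytest.fixture(scope="session")
def net_params():
    # grid step of network templates; d_rel from the pulse calibration at
    # that step (frozen here to keep the suite fast, verified in test_drive)
    return ParameterSet(dx=0.55, d_rel=0.0598)


def make_uniform_disc_template(radius_um=5.0, r_value=1.0, pixel_size=0.55,
                               pad_um=2.0):
    """Uniform-AVF disc: the simplest non-trivial template."""
    n = int(2 * (radius_um + pad_um) / pixel_size)
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2
    d = np.hypot(yy - c, xx - c) * pixel_size
    img = np.where(d <= radius_um, r_value, 0.0)
    from astroca.morphology import AVFMap

    return encode_template(AVFMap(r=img, pixel_size=pixel_size))
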