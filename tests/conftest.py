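import numpy as np
import pytest

import blockface as bf


@pytest.fixture(scope="session")
def epon():
    return bf.epon_araldite()


@pytest.fixture(scope="session")
def ga25(epon):
    return bf.substitute_ga_for_c(epon, 0.25)


@pytest.fixture(scope="session")
def ga50(epon):
    return bf.substitute_ga_for_c(epon, 0.50)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def depth_series_images():
    """Depth-series BSE images rendered at the full study conditions
    (1.5 keV, 3000 trajectories/pixel, 3-nm pixels), one per Ga level.

    Session-scoped: these are the most expensive renders in the suite and are
    shared by the visibility and acceptance tests.
    """
    from blockface.imaging import OPEN_DETECTOR, render_bse_image
    from blockface.mc import SimConfig
    from blockface.phantoms import depth_series_phantom

    out = {}
    for ga in (0.0, 0.25, 0.50):
        ph = depth_series_phantom(ga_fraction=ga)
        scan = ph.default_scan()
        img = render_bse_image(ph, scan, OPEN_DETECTOR, SimConfig(seed=101))
        out[ga] = (ph, scan, img)
    return out
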