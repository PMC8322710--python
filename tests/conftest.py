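import numpy as np
import pytest

from oculotamp import geometry as G


@pytest.fixture(scope="session")
def sphere_geom():
    """Lens-free sphere, coarse (fast) resolution, segmented."""
    return G.segment_regions(
        G.build_chamber_mesh(lens_radius=None, lens_center_offset=None, resolution=1.0)
    )


@pytest.fixture(scope="session")
def eye_geom():
    """Default phakic chamber (lens indentation), coarse resolution."""
    return G.segment_regions(G.build_chamber_mesh(resolution=1.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210722)
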