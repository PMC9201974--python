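import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phantomqc.datatypes import IRF, OpticalProperties, RandomStream, SlabGeometry
from phantomqc.inversion import build_lut
from phantomqc.transport import simulate_white_dtof

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def slab_geom():
    """2-cm slab, full transmitted collection (infinite detector disc)."""
    return SlabGeometry(thickness_cm=2.0, detector_radius_cm=np.inf)


@pytest.fixture(scope="session")
def white_props():
    return OpticalProperties(mu_a=0.0, mu_sp=10.0, g=0.0, n_in=1.54)


@pytest.fixture(scope="session")
def white_mc_200k(white_props, slab_geom):
    """Shared white MC run (2e5 photons) reused across transport tests."""
    return simulate_white_dtof(
        white_props, slab_geom, 200_000, bin_width_ps=10.0, t_max_ps=6000.0,
        stream=RandomStream(7),
    )


@pytest.fixture(scope="session")
def diffusion_lut(slab_geom):
    """Full-range white LUT from the diffusion engine (fast, noise-free)."""
    return build_lut(0.1, 20.0, 0.1, slab_geom, engine="diffusion")


@pytest.fixture(scope="session")
def narrow_lut(slab_geom):
    """Narrow LUT around physiological mu_sp for cheap per-position fits."""
    return build_lut(8.0, 11.0, 0.1, slab_geom, engine="diffusion")


@pytest.fixture(scope="session")
def irf35():
    return IRF.gaussian(35.0)
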