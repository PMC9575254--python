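import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150301)


@pytest.fixture(scope="session")
def fine_sphere_phantom():
    """0.5 mm isotropic phantom holding one r=10 mm sphere lesion."""
    from pasmri.phantom import Ellipsoid, PhantomConfig, build_phantom

    cfg = PhantomConfig(spacing=(0.5, 0.5, 0.5), shape=(192, 192, 192),
                        dib_ellipsoids=[Ellipsoid((48.0, 48.0, 62.0), (10.0, 10.0, 10.0))])
    return build_phantom(cfg, seed=1)


@pytest.fixture(scope="session")
def table2_geometries():
    """Three-plane geometry at the study protocol: 5 mm slices, 1 mm gap,
    400 mm FOV on a 256 matrix."""
    from pasmri.phantom import default_geometries

    return default_geometries(slice_thickness=5.0, slice_gap=1.0,
                              in_plane=400.0 / 256.0)
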