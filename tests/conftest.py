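import numpy as np
import pytest
from shapely.geometry import box

from legrange import OccupancyGLMM, generate_world, paper_calibrated_config
from legrange.ranges import Gazetteer, RegionPolygon

#: moderate, well-identified generating conditions for fast fitting tests
MODERATE_COEFS = dict(
    intercept=-2.0,
    symbiosis=-0.5,
    abs_latitude=0.15,
    native_area=0.2,
    annual=0.8,
    woody=0.3,
    n_uses=0.4,
    region_area=0.05,
    symbiosis_x_uses=0.15,
)


def moderate_config(**overrides):
    base = dict(
        n_species=200,
        n_regions=20,
        n_genera=40,
        coefficients=dict(MODERATE_COEFS),
        v_species=1.0,
        v_region=0.5,
        seed=3,
    )
    base.update(overrides)
    base.setdefault("n_tribes", max(1, base["n_genera"] // 4))
    return paper_calibrated_config("all_species").with_(**base)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(moderate_config())


@pytest.fixture(scope="session")
def small_fit(small_world):
    res = OccupancyGLMM.from_world(small_world).fit()
    assert res.converged
    return res


@pytest.fixture()
def toy_gazetteer():
    """Two regions under one continent; one region has a listed area."""
    units = [
        RegionPolygon("c0", "Continent 0", "continent", None, box(0, 0, 20, 10)),
        RegionPolygon("r0", "Northland", "region", "c0", box(0, 0, 10, 10)),
        RegionPolygon("r1", "Southland", "region", "c0", box(10, 0, 20, 10)),
        RegionPolygon("r0a0", "Northland West", "area", "r0", box(0, 0, 5, 10)),
    ]
    return Gazetteer(units)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
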