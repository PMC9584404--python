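"""Shared fixtures: small analytic fields, zones and releases."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from leptoflow.larval_ibm import BioRules
from leptoflow.settlement import SettlementZone
from leptoflow.synthetic_ocean import (
    FieldScenario,
    GridSpec,
    Gyre,
    TwoLayerTemperature,
    UniformCurrent,
    render_field,
)

THREE_DAYS = 3 * 86_400.0


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(lon=(-78.0, -76.0, 41), lat=(23.0, 25.0, 41),
                    depth=(200.0, 21), time=(THREE_DAYS, 4))


@pytest.fixture(scope="session")
def still_field(small_grid):
    """No currents, two-layer stratification, no land."""
    return render_field(FieldScenario(), small_grid)


@pytest.fixture(scope="session")
def uniform_field(small_grid):
    """0.1 m/s due east everywhere."""
    return render_field(
        FieldScenario(currents=(UniformCurrent(0.1, 90.0),)), small_grid)


@pytest.fixture(scope="session")
def gyre_field(small_grid):
    """Solid-body gyre, 20 km core, 0.2 m/s peak tangential speed."""
    gyre = Gyre(lon=-77.0, lat=24.0, radius_m=20_000.0, peak_speed=0.2,
                sense=1, kind="solid_body")
    return render_field(FieldScenario(gyres=(gyre,)), small_grid)


@pytest.fixture(scope="session")
def rules():
    return BioRules()


@pytest.fixture()
def square_zones():
    """Two unit squares with island labels A and B, plus a triangle C."""
    return [
        SettlementZone("z0", "A", Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])),
        SettlementZone("z1", "B", Polygon([(2, 0), (3, 0), (3, 1), (2, 1)])),
        SettlementZone("z2", "C", Polygon([(5, 5), (6, 5), (5.5, 6)])),
    ]


@pytest.fixture()
def disc_zone():
    return [SettlementZone("d0", "Disc", Point(-77.0, 24.0).buffer(0.2))]
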