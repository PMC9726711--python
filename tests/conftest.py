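from datetime import timedelta

import numpy as np
import pytest

from tedrecon.inhalation import CoefficientTable
from tedrecon.plume import FORMS, ConcentrationField, GridSpec
from tedrecon.trajectory import ExposureWindow, MicroEnv, Waypoint


@pytest.fixture(scope="session")
def window() -> ExposureWindow:
    return ExposureWindow()


@pytest.fixture(scope="session")
def coefficients() -> CoefficientTable:
    return CoefficientTable.default()


@pytest.fixture
def small_grid() -> GridSpec:
    # 4x4 cells of ~1 km over the coastal study area
    return GridSpec(37.40, 140.90, 0.009, 0.0113, 4, 4)


@pytest.fixture
def uniform_field(small_grid, window) -> ConcentrationField:
    vals = np.ones((window.n_hours, small_grid.n_rows, small_grid.n_cols, len(FORMS)))
    return ConcentrationField(small_grid, vals, window)


def make_waypoint(window, hours_after_start, lat, lon, env=MicroEnv.INDOOR):
    return Waypoint(window.start + timedelta(hours=hours_after_start), lat, lon, env)


@pytest.fixture
def stationary_waypoints(window):
    return [
        make_waypoint(window, 0, 37.42, 140.93),
        make_waypoint(window, window.n_hours, 37.42, 140.93),
    ]
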