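from datetime import date

import numpy as np
import pytest

from whcns.io_cli import (generate_weather, load_bundled_crops,
                          load_bundled_soil, load_default_n_params)
from whcns.soil_water import HydraulicParams, SoilGrid, SoilLayerSpec


@pytest.fixture(scope="session")
def bundled_layers():
    return load_bundled_soil()


@pytest.fixture(scope="session")
def bundled_crops():
    return load_bundled_crops()


@pytest.fixture(scope="session")
def default_n_params():
    return load_default_n_params()


@pytest.fixture
def loam_params():
    """Generic loam for numeric tests."""
    return HydraulicParams(theta_r=0.05, theta_s=0.40, alpha=0.02, n=1.5,
                           K_s=50.0)


@pytest.fixture
def loam_column(loam_params):
    layer = SoilLayerSpec(top=0.0, bottom=300.0, bulk_density=1.4,
                          sand=40.0, silt=40.0, clay=20.0,
                          hydraulic=loam_params)
    return SoilGrid([layer], dz=5.0, profile_depth=300.0)


@pytest.fixture(scope="session")
def one_year_weather():
    return generate_weather(date(2000, 1, 1), 366, seed=11)
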