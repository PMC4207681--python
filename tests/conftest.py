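import numpy as np
import pytest

from fallowsim import (
    LandscapeConfig,
    PreparedLandscape,
    generate_landscape,
    make_default_factors,
)


@pytest.fixture(scope="session")
def desk_landscape():
    """Default desk-scale landscape (200x200 cells, 300 parcels)."""
    return generate_landscape(LandscapeConfig(), seed=1)


@pytest.fixture(scope="session")
def desk_prepared(desk_landscape):
    return PreparedLandscape(desk_landscape)


@pytest.fixture(scope="session")
def small_landscape():
    """Small landscape for fast per-run tests."""
    cfg = LandscapeConfig(rows=80, cols=80, parcel_count=60)
    return generate_landscape(cfg, seed=11)


@pytest.fixture(scope="session")
def small_prepared(small_landscape):
    return PreparedLandscape(small_landscape)


@pytest.fixture()
def specs():
    return make_default_factors()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
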