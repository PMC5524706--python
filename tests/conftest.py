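import numpy as np
import pytest
from hypothesis import settings

from velutina import (
    DemographyParams,
    DispersalParams,
    SuitabilityWeights,
    gb_like_landscape,
    homogeneous_landscape,
)
from velutina.landscape import LandscapeSpec, generate_landscape
from velutina import riskmap as rm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gb2():
    """GB-like landscape at 2-km cells (risk-map default)."""
    return gb_like_landscape(cell_km=2.0)


@pytest.fixture(scope="session")
def gb4():
    """GB-like landscape at 4-km cells (coarsened, for the fixed-point solve)."""
    return gb_like_landscape(cell_km=4.0)


@pytest.fixture(scope="session")
def dem():
    return DemographyParams()


@pytest.fixture(scope="session")
def disp():
    return DispersalParams()


@pytest.fixture(scope="session")
def weights():
    return SuitabilityWeights()


@pytest.fixture(scope="session")
def gb2_observations(gb2):
    return rm.default_observations(gb2)


@pytest.fixture(scope="session")
def gb2_posterior(gb2, gb2_observations, weights, disp):
    return rm.founder_posterior(gb2_observations, gb2, weights, disp)


@pytest.fixture(scope="session")
def small_homog():
    """400 x 400 km fully-suitable landscape at constant French latitude."""
    return homogeneous_landscape(width_km=400.0, cell_km=4.0)


@pytest.fixture(scope="session")
def patchy():
    """Small heterogeneous landscape (all four land classes, no water body
    except a thin coast) used for settlement-kernel consistency checks."""
    spec = LandscapeSpec(
        n_rows=120,
        n_cols=120,
        cell_size_km=2.0,
        proportions={"water": 0.08, "urban": 0.15, "agricultural": 0.45, "woodland": 0.2},
        patch_scale_km=8.0,
    )
    return generate_landscape(spec, seed=7)


def three_sigma_mean(samples) -> tuple[float, float]:
    """(sample mean, 3 x standard error)."""
    samples = np.asarray(samples, dtype=float)
    return float(samples.mean()), 3.0 * float(samples.std(ddof=1)) / np.sqrt(samples.size)
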