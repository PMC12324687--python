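import numpy as np
import pytest

from perfmap import CohortConfig, geometry, simulate_cohort
from perfmap.nulls import spin_assignments, vasa_assignments


@pytest.fixture(scope="session")
def centroids400():
    return geometry.fibonacci_sphere(400)


@pytest.fixture(scope="session")
def distances400(centroids400):
    return geometry.great_circle_distance(centroids400)


@pytest.fixture(scope="session")
def spin1000(centroids400):
    """Shared 1000-spin ensemble on the 400-parcel sphere (geometry-only)."""
    return spin_assignments(centroids400, 1000, seed=99)


@pytest.fixture(scope="session")
def vasa1000(centroids400):
    return vasa_assignments(centroids400, 1000, seed=99)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortConfig(seed=11))
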