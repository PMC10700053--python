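import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from breedopt import BudgetModel, ParameterBounds
from breedopt.evaluation import SyntheticObjective

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bounds():
    return ParameterBounds()


@pytest.fixture(scope="session")
def budget():
    return BudgetModel()


@pytest.fixture(scope="session")
def quadratic_objective():
    """Synthetic noisy objective with a known composite optimum at (400, 15)."""
    return SyntheticObjective.quadratic()


@pytest.fixture(scope="session")
def full_axes(bounds):
    return (
        np.arange(bounds.x2_min, bounds.x2_max + 1, dtype=float),
        np.arange(bounds.x3_min, bounds.x3_max + 1, dtype=float),
    )
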