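import numpy as np
import pytest
from hypothesis import settings

from agemort.model_core import AgeTimeGrid, ToyParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from agemort.sud_model import AgeBinSchema, PopulationModel, SUDParams


@pytest.fixture(scope="session")
def toy_params() -> ToyParams:
    """The reference data-generating rates of the closed-form model."""
    return ToyParams(mu=0.08, lam=0.2)


@pytest.fixture(scope="session")
def sud_params() -> SUDParams:
    """Reference overdose-model parameters (addiction-age mean 45 years)."""
    return SUDParams(
        mu=7e-4, r0=0.04, alpha1=15.0, beta1=1.0 / 3.0, alpha2=15.0, beta2=1.0 / 3.0
    )


@pytest.fixture(scope="session")
def population() -> PopulationModel:
    return PopulationModel.from_calendar()


@pytest.fixture(scope="session")
def schema() -> AgeBinSchema:
    return AgeBinSchema.cdc_22()


@pytest.fixture(scope="session")
def fine_grid() -> AgeTimeGrid:
    """The reference discretisation: [0, 120] years, 1000 cells, dt=0.1."""
    return AgeTimeGrid(a_max=120.0, n_age=1000, delta_t=0.1, n_time=100)


@pytest.fixture(scope="session")
def coarse_grid() -> AgeTimeGrid:
    """A cheap grid for filter-level tests."""
    return AgeTimeGrid(a_max=120.0, n_age=200, delta_t=0.1, n_time=50)
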