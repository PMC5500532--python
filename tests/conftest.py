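import numpy as np
import pytest

from mbdiv import (
    CovariateTrajectory,
    EpochGrid,
    LineageRecord,
    MBDModel,
)
from mbdiv.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def two_lineages():
    """The worked pair: one extant (10, 0) and one extinct (6, 2)."""
    return [LineageRecord("A", 10.0, 0.0), LineageRecord("B", 6.0, 2.0)]


@pytest.fixture
def epoch_grid():
    return EpochGrid(np.array([10.0, 5.0, 0.0]))


@pytest.fixture
def unit_covariate():
    """A rescaled covariate fixed at 1 over [0, 20] Ma."""
    return CovariateTrajectory(
        "unit", np.array([20.0, 0.0]), np.array([1.0, 1.0]), rescaled=True
    )


@pytest.fixture
def ramp_covariate():
    """A rescaled covariate ramping 1 (oldest) -> 0 (present)."""
    return CovariateTrajectory(
        "ramp", np.array([20.0, 0.0]), np.array([1.0, 0.0]), rescaled=True
    )


@pytest.fixture(scope="session")
def recovery_dataset():
    """One simulated dataset under the standard recovery condition
    (exponential model, 5 covariates, true H_1 = 2.5)."""
    return simulate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def recovery_fit(recovery_dataset):
    """A moderately long exponential-MBD fit of the recovery dataset,
    shared by summary/diagnostic tests."""
    lineages, covset, _ = recovery_dataset
    model = MBDModel(lineages, covset, mode="exponential")
    return model.fit(n_iter=50_000, sample_freq=50, seed=11)
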