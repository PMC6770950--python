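import numpy as np
import pytest

import rennetmon as rm


@pytest.fixture(scope="session")
def times30() -> np.ndarray:
    return rm.default_times()


@pytest.fixture(scope="session")
def small_grid() -> np.ndarray:
    """A coarse 220-point wavenumber grid covering the analysis window."""
    return np.linspace(12500.0, 5824.0, 220)


@pytest.fixture(scope="session")
def center_kinetics() -> rm.KineticParams:
    return rm.KineticParams(transition_time=7.0)


@pytest.fixture(scope="session")
def noiseless_truth(center_kinetics, times30, small_grid):
    return rm.make_ground_truth(
        center_kinetics, times=times30, wavenumbers=small_grid, noise_sd=0.0
    )


@pytest.fixture(scope="session")
def noiseless_batch(noiseless_truth):
    return rm.simulate_batch(noiseless_truth, seed=1)


@pytest.fixture(scope="session")
def raw_fit_config() -> rm.ConstraintConfig:
    """Constraints for resolving raw absorbance (nonnegative spectra)."""
    return rm.ConstraintConfig(nonneg_S=True, max_iterations=150)
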