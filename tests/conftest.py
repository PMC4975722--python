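import numpy as np
import pytest

from smtdwi import DPMHyper, MicroParams, generate_uniform_scheme

# Simulation ground truth used throughout: a strongly anisotropic white
# matter voxel (lam_par=2.5, lam_perp=0.1 um^2/ms).
TRUTH = MicroParams(2.5, 0.1)

# Exact powder averages of TRUTH at the two protocol shells (computed from
# the closed form; print to 3 decimals as 0.503 / 0.282).
MEAN_B1 = 0.5028873083286475
MEAN_B25 = 0.2816207083240291


@pytest.fixture(scope="session")
def truth() -> MicroParams:
    return TRUTH


@pytest.fixture(scope="session")
def hyper() -> DPMHyper:
    return DPMHyper()


@pytest.fixture(scope="session")
def protocol_scheme():
    """Two-shell protocol: 76 + 75 directions at b = 1.0 / 2.5 ms/um^2, 10 b0s."""
    return generate_uniform_scheme([76, 75], [1.0, 2.5], n_b0=10, rng_seed=0)


@pytest.fixture(scope="session")
def small_scheme():
    """Cheap two-shell scheme for volume-level tests."""
    return generate_uniform_scheme([16, 16], [1.0, 2.5], n_b0=4, rng_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
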