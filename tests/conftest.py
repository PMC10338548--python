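import numpy as np
import pytest

from nucleophase.dynamics import KineticParams
from nucleophase.equilibrium import calibrate_defaults
from nucleophase.free_energy import FreeEnergyParams
from nucleophase.geometry import build_domain


@pytest.fixture(scope="session")
def fe_default():
    """Calibrated default free energy (re-entrant couplings)."""
    return calibrate_defaults()


@pytest.fixture(scope="session")
def fe_pure():
    """Pure protein double well: RNA fully decoupled."""
    return FreeEnergyParams(rho_P=1.0, alpha=0.1, beta=0.7, chi=0.0,
                            c_rep=0.0, rho_R=1.0, kappa=0.08)


@pytest.fixture(scope="session")
def kin_default():
    return KineticParams(M_p=1.0, M_r=1.0, k_d=0.5)


@pytest.fixture(scope="session")
def domain_test():
    """Reduced test-scale disk: radius 15, dx 0.4."""
    return build_domain(15.0, 0.4)


@pytest.fixture(scope="session")
def domain_tiny():
    """Tiny disk for oracle comparisons: radius 5, dx 0.5."""
    return build_domain(5.0, 0.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
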