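import numpy as np
import pytest

from massfield import EIParams, FieldParams, MassParams


@pytest.fixture(scope="session")
def fig2_mass() -> MassParams:
    """Mean-field validation regime (network comparison)."""
    return MassParams(eta0=2.0, gamma=0.5, tau=16.0, kappa_v=1.0, kappa_s=1.0,
                      alpha=0.5)


@pytest.fixture(scope="session")
def single_pop_osc() -> MassParams:
    """Single-population limit-cycle regime."""
    return MassParams(eta0=1.0, kappa_v=1.2, kappa_s=1.0, tau=15.0, alpha=0.5,
                      gamma=0.5)


@pytest.fixture(scope="session")
def field_mass_1d() -> MassParams:
    """Mass parameters of the 1D wave-instability regime."""
    return MassParams(eta0=1.0, kappa_s=10.0, tau=15.0, alpha=0.5, gamma=0.5,
                      kappa_v=0.85)


@pytest.fixture(scope="session")
def field_1d(field_mass_1d) -> FieldParams:
    return FieldParams(mass=field_mass_1d, c=1.0, dim=1, L=40 * np.pi, n=256)


@pytest.fixture(scope="session")
def ei_inhibitory_gaps() -> EIParams:
    """E-I regime with gap junctions in the inhibitory population only."""
    return EIParams(kappa_v_E=0.0, kappa_v_I=0.5)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
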