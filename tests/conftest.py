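import pytest

from ivimr2.acquisition import (IVIMParams, MonoexpDecayParams,
                                default_protocols)
from ivimr2.simulate import NoiseSpec, default_phantom_spec


@pytest.fixture(scope="session")
def protocols():
    return default_protocols()


@pytest.fixture(scope="session")
def dwi(protocols):
    return protocols[0]


@pytest.fixture(scope="session")
def gre(protocols):
    return protocols[1]


@pytest.fixture(scope="session")
def baseline_ivim():
    """Tumor-baseline IVIM truth (reference study, pre-treatment ROI)."""
    return IVIMParams(S0=1000.0, D=0.556e-3, Dstar=8.53e-3, f=0.1675)


@pytest.fixture(scope="session")
def baseline_decay():
    return MonoexpDecayParams(S0=1000.0, R2star=24.74)


@pytest.fixture(scope="session")
def default_phantom():
    """(PhantomSpec, NoiseSpec) at the default SNR-50 Rician noise."""
    return default_phantom_spec()


@pytest.fixture(scope="session")
def noiseless():
    return NoiseSpec(model="none", sigma=0.0, seed=0)
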