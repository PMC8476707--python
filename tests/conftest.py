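import numpy as np
import pytest

from aavcdms.capsid import VPStoichiometry
from aavcdms.genome import PackagingState
from aavcdms.instrument import ChargeModel, InstrumentConfig
from aavcdms.simulate import MixtureComponent


@pytest.fixture
def aav8():
    return VPStoichiometry((81667.0, 66692.0, 59805.0), (1.0, 1.0, 10.0), 60)


@pytest.fixture
def instrument():
    return InstrumentConfig()


@pytest.fixture
def quiet_instrument():
    """No m/z error, no flagged events: mass error is the charge term only."""
    return InstrumentConfig(rel_sigma_mz=0.0, multiple_ion_rate=0.0, short_trap_rate=0.0)


@pytest.fixture
def charge_model():
    return ChargeModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_component(aav8, kind="empty", dna_mass=0.0, weight=1.0, label=None, **kw):
    state = PackagingState(kind=kind, dna_mass=dna_mass)
    return MixtureComponent(
        label=label or kind, packaging_state=state, capsid=aav8, weight=weight, **kw
    )
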