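import numpy as np
import pytest

from dropletkd.equilibrium import EquilibriumSystem

# Reference system: standard assay concentrations (1.66/1.25 uM), a 1 um
# reaction layer on a 22.5 um droplet, K_D = 0.5 uM.  Expected values were
# computed with an independent brentq root-find on the mass-action +
# conservation system and frozen here.
REF_T_EQ = 1.0979232271726906
REF_RATIO = 2.038848407590361
REF_C_EQ = 1.1405757962048195


@pytest.fixture
def ref_system() -> EquilibriumSystem:
    return EquilibriumSystem(S_tot=1.66, T_tot=1.25, K_D=0.5, eps=1.0, r0=22.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
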