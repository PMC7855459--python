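import numpy as np
import pytest

from batchphys.core import GasConditions
from batchphys.synthetic import NoiseModel, StrainPreset, simulate_batch


@pytest.fixture
def zero_noise():
    return NoiseModel(rel_sd_biomass=0.0, rel_sd_glucose=0.0, abs_sd_gas_volpct=0.0, seed=0)


@pytest.fixture
def wt_preset():
    """Wild-type-like physiology on 1 % glucose."""
    return StrainPreset()


@pytest.fixture
def noiseless_dataset(wt_preset, zero_noise):
    return simulate_batch(wt_preset, zero_noise)


@pytest.fixture
def noisy_dataset(wt_preset):
    return simulate_batch(wt_preset, NoiseModel(seed=42))


@pytest.fixture
def gas_example():
    """Air at 0.06 m3/h, lab bench conditions."""
    return GasConditions(F=0.06, p=101325.0, T=298.15, phi_o2_in=20.95, phi_co2_in=0.04)
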