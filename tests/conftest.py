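import numpy as np
import pytest

from clefmap.lattice_model import LigandParams
from clefmap.synthetic_data import GeneratorConfig


@pytest.fixture
def params():
    """Moderate-affinity parameters usable with enumeration."""
    return LigandParams(K_a=1e6, omega=1e3)


@pytest.fixture
def strong_params():
    return LigandParams(K_a=1e8, omega=1e10)


@pytest.fixture
def fast_config():
    """Small generator configuration for quick round trips."""
    return GeneratorConfig(
        constructs=("21T9",),
        cd_constructs=("21T8,9",),
        replicates_fluorescence=2,
        replicates_quench=2,
        cd_scans=4,
        wavelength_step=5.0,
        seed=7,
    )


@pytest.fixture
def noise_free_config():
    return GeneratorConfig(
        constructs=("21T9",),
        cd_constructs=("21T8,9",),
        noise_rel=0.0,
        replicates_fluorescence=1,
        replicates_quench=1,
        cd_scans=2,
        wavelength_step=5.0,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
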