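import numpy as np
import pytest

from cmcfit import MicellizationParams
from cmcfit.synthetic import GridSpec, NoiseSpec, simulate_curve

# SDS-like conductivity parameters (cmc in mM, slopes in uS/cm per mM)
SDS = {"cmc": 8.099, "r": 0.112, "a": 66.74, "b": 26.43, "kappa_s": 0.0}

# TX100-like dye-binding fluorescence parameters (cmc in mM)
TX100_FLUOR = {"cmc": 0.27, "r": 0.15, "k_per_s": 200.0, "f_free": 1.0, "f_bound": 10.0}


@pytest.fixture
def sds_params():
    return dict(SDS)


@pytest.fixture
def mic_typical():
    return MicellizationParams(cmc=8.099, r=0.112)


@pytest.fixture
def sds_noiseless():
    return simulate_curve("conductivity", SDS, GridSpec(0.0, 16.2, 200))


@pytest.fixture
def sds_noisy():
    return simulate_curve(
        "conductivity",
        SDS,
        GridSpec(0.05, 16.2, 100),
        NoiseSpec(sd=0.005, mode="relative", seed=11),
    )
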