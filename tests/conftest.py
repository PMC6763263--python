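"""Shared fixtures: printed wild-type / mutant parameters and model specs."""

import numpy as np
import pytest

from bkgating.camodels import AllostericModelSpec, SiteConfig
from bkgating.kinetics import TwoStateRates
from bkgating.qv import BoltzmannParams

# Boltzmann fits of the wild-type fast-charge Q-V at the two extreme Ca2+
# conditions (saturating = 100 uM).
WT_ZERO = dict(vh=174.5, zq=0.60)
WT_SAT = dict(vh=31.9, zq=0.66)

# Two-state rate fits of tau_IG-ON(V) at the same conditions (zJ fixed to
# the Q-V valence).
RATES_ZERO = dict(alpha0=3.73, beta0=76.10, delta=0.29, zj=0.60)
RATES_SAT = dict(alpha0=7.28, beta0=6.98, delta=0.36, zj=0.66)

# Reference parameter set used for scheme-comparison figures:
# zJ = 0.58, J0 = 0.018, KD = 11 uM, saturating factor E = 25.
DEMO = dict(zj=0.58, j0=0.018, kd=11.0, e=25.0)


@pytest.fixture
def wt_zero_params() -> BoltzmannParams:
    return BoltzmannParams(**WT_ZERO)


@pytest.fixture
def wt_sat_params() -> BoltzmannParams:
    return BoltzmannParams(**WT_SAT)


@pytest.fixture
def rates_zero() -> TwoStateRates:
    return TwoStateRates(**RATES_ZERO)


@pytest.fixture
def rates_sat() -> TwoStateRates:
    return TwoStateRates(**RATES_SAT)


@pytest.fixture
def scheme1_demo() -> AllostericModelSpec:
    return AllostericModelSpec(
        scheme="I", sites=SiteConfig(kd=DEMO["kd"]),
        zj=DEMO["zj"], j0=DEMO["j0"], e_factor=DEMO["e"], label="scheme I demo",
    )


@pytest.fixture
def scheme2_demo() -> AllostericModelSpec:
    return AllostericModelSpec(
        scheme="II", sites=SiteConfig(kd=DEMO["kd"]),
        zj=DEMO["zj"], j0=DEMO["j0"], e_factor=DEMO["e"], label="scheme II demo",
    )


@pytest.fixture
def v_protocol() -> np.ndarray:
    """Step potentials of the recording protocol: -90..350 mV in 10-mV steps."""
    return np.arange(-90.0, 351.0, 10.0)
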