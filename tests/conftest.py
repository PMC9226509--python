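import numpy as np
import pytest

from vfret import PhotophysicsParams, simulate_cohort
from vfret.presets import get_preset
from vfret.simulator import KINETICS_ALEX


@pytest.fixture
def noiseless_phys():
    """Deterministic photophysics: no noise, no leakage, no bleaching."""
    return PhotophysicsParams(noise_sd=0.0, leakage_l=0.0,
                              k_bleach_donor=0.0, k_bleach_acceptor=0.0,
                              alex_pattern=KINETICS_ALEX)


@pytest.fixture
def default_phys():
    return PhotophysicsParams(alex_pattern=KINETICS_ALEX)


@pytest.fixture(scope="session")
def g4_cohort():
    """Shared default-noise vf-G4 kinetics cohort (n=150)."""
    phys = PhotophysicsParams(alex_pattern=KINETICS_ALEX)
    return simulate_cohort(get_preset("vf-G4"), phys, n=150, seed=1234,
                           duration_s=40.0)


@pytest.fixture(scope="session")
def g4_cohort_noiseless():
    """Shared noiseless vf-G4 cohort for exact-inversion checks (n=60)."""
    phys = PhotophysicsParams(noise_sd=0.0, leakage_l=0.0,
                              k_bleach_donor=0.0, k_bleach_acceptor=0.0,
                              alex_pattern=KINETICS_ALEX)
    return simulate_cohort(get_preset("vf-G4"), phys, n=60, seed=4321,
                           duration_s=40.0)


def seeded_rng(seed=0):
    return np.random.default_rng(seed)
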