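"""Shared fixtures: small simulated cohorts built once per session."""

import numpy as np
import pytest

from netcog import NetworkCoupling, default_config, simulate_cohort

#: compact vertex layout used by most tests: 30 vertices per network + 14 unlabeled
SMALL_SIZES = np.array([14, 30, 30, 30, 30, 30, 30, 30])


def small_config(**overrides):
    defaults = dict(n_vertices=224, network_sizes=SMALL_SIZES.copy())
    defaults.update(overrides)
    return default_config(**defaults)


def planted_net7_coupling(strength=0.4, age_coupling=-0.2):
    tf = np.zeros((7, 2))
    tf[6, 0] = strength
    return NetworkCoupling(tf, np.full(7, age_coupling), np.zeros((7, 2)))


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size (n=165, V=2000) cohort with no planted couplings."""
    return simulate_cohort(default_config(seed=101))


@pytest.fixture(scope="session")
def planted_cohort():
    """Compact cohort with thickness-ability coupling 0.4 in the default-mode
    network only."""
    cfg = small_config(network_coupling=planted_net7_coupling(), seed=202)
    return simulate_cohort(cfg)
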