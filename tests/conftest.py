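"""Shared fixtures.

The expensive simulations (converged 20-cycle run, enrichment run) are
session-scoped and shared between the unit suite and the acceptance tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from yeastff import (
    YeastModel,
    default_protocol,
    load_calibrated_parameters,
    load_chemostat_state,
    load_reference_parameters,
    run_cycles,
)


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def calibrated_params():
    return load_calibrated_parameters()


@pytest.fixture(scope="session")
def reference_params():
    return load_reference_parameters()


@pytest.fixture(scope="session")
def chemostat_state():
    return load_chemostat_state("calibrated")


@pytest.fixture(scope="session")
def calibrated_model(calibrated_params, protocol):
    return YeastModel(calibrated_params, protocol.biomass_gdw_per_l,
                      protocol.vacuole_fraction)


@pytest.fixture(scope="session")
def converged_traj(chemostat_state, calibrated_params, protocol,
                   calibrated_model):
    """Full 20-cycle feast/famine simulation from the chemostat state."""
    return run_cycles(chemostat_state, calibrated_params, protocol,
                      model=calibrated_model, n_cycles=20)


@pytest.fixture(scope="session")
def short_traj(chemostat_state, calibrated_params, protocol, calibrated_model):
    """Three cycles at 2 s output resolution, for cheaper checks."""
    return run_cycles(chemostat_state, calibrated_params, protocol,
                      model=calibrated_model, n_cycles=3, t_res=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_admissible_states(rng, n, model):
    """Log-uniform positive concentrations in physiological ranges."""
    n_s = model.i_vol
    lo, hi = np.log(1e-4), np.log(20.0)
    y = np.exp(rng.uniform(lo, hi, size=(n, n_s)))
    return np.hstack([y, np.full((n, 1), 2.0)])
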