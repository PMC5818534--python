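"""Shared fixtures: synthetic cells and their simulated protocol batteries.

Session scope keeps the expensive simulations (protocol generation runs the
ground-truth model across ~20 sweeps) to one execution per test run.
"""

import pytest

from neurofit.biophys_sim import PassiveParameters
from neurofit.ephys_features import aggregate_targets, sweep_features
from neurofit.morphology import KINDS, discretize, make_ball_and_stick
from neurofit.objective import default_tolerances
from neurofit.synthetic_data import generate_protocol, make_cell, training_sweeps


@pytest.fixture(scope="session")
def ball_and_stick():
    return discretize(make_ball_and_stick(6.0, 300.0, 2.0))


@pytest.fixture(scope="session")
def uniform_passive():
    return PassiveParameters(cm_by_kind={k: 1.0 for k in KINDS}, ri=120.0,
                             g_leak_by_kind={k: 1 / 12000.0 for k in KINDS},
                             e_leak=-77.0)


@pytest.fixture(scope="session")
def rs_cell():
    """Regular-spiking ground-truth cell (wide spikes, conductance set A)."""
    return make_cell("regular_spiking", seed=1)


@pytest.fixture(scope="session")
def fs_cell():
    """Fast-spiking ground-truth cell (narrow spikes, conductance set B)."""
    return make_cell("fast_spiking", seed=2)


@pytest.fixture(scope="session")
def rs_sweeps(rs_cell):
    return generate_protocol(rs_cell)


@pytest.fixture(scope="session")
def rs_targets(rs_sweeps):
    reps = training_sweeps(rs_sweeps)
    return aggregate_targets([sweep_features(s) for s in reps],
                             default_tolerances())


@pytest.fixture(scope="session")
def rs_model(rs_cell):
    return rs_cell.build()
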