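"""Shared fixtures: the default synthetic population/table and calibrations.

The default study conditions — a 117-neuron population with the default
tuning distributions, reduced on the default 9-level strength grid with 10
recording trials per condition — are built once per session; model
parameters matched to the behavioral switch-ratio target of 0.70 are
derived from that table once and shared by the tests that need them.
"""

import numpy as np
import pytest

from taskswitch import calibration
from taskswitch import synthetic_mt as smt

POP_SEED = 101
TABLE_SEED = 202

#: grid for SR-only simulations (5 levels per feature)
LEVELS5 = np.array([-0.5, -0.125, 0.0, 0.125, 0.5])
#: grid for threshold analyses (3 nonzero absolute levels)
LEVELS7 = np.array([-0.5, -0.25, -0.0625, 0.0, 0.0625, 0.25, 0.5])
#: weak-strength grid for choice-probability runs
LEVELS_CP = np.array([-0.125, -0.0625, 0.0, 0.0625, 0.125])


@pytest.fixture(scope="session")
def default_population():
    return smt.make_population(117, seed=POP_SEED)


@pytest.fixture(scope="session")
def default_table(default_population):
    return smt.build_rate_table(default_population, trials_per_condition=10,
                                seed=TABLE_SEED)


@pytest.fixture(scope="session")
def small_table():
    """A fast 8-neuron table on the 5-level grid for unit tests."""
    pop = smt.make_population(8, seed=7)
    return smt.build_rate_table(pop, levels=LEVELS5, trials_per_condition=5,
                                seed=8)


@pytest.fixture(scope="session")
def calibrated_w(default_table):
    """Gated-model weight matched to the behavioral SR target of 0.70."""
    res = calibration.calibrate_weight(
        default_table, 0.70, levels=LEVELS5, trials_per_condition=200,
        seed=303)
    return res.best


@pytest.fixture(scope="session")
def calibrated_tau(default_table):
    """Gate/leak time constant (ms) matched to the SR target of 0.70."""
    res = calibration.calibrate_time_constant(
        default_table, 0.70, levels=LEVELS5, trials_per_condition=200,
        seed=404)
    return res.best
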