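"""Shared fixtures: simulated units and stimuli reused across test modules.

Everything is generated at test time from fixed seeds; the heavier
population fixtures are session-scoped so the acceptance-style tests can
share one simulation.
"""

import warnings

import numpy as np
import pytest

from endbulb.simulate import UnitConfig, Silence, simulate_unit
from endbulb.stimuli import generate_rgs, generate_fra_protocol

warnings.filterwarnings("ignore", message="correlogram peak")


@pytest.fixture(scope="session")
def default_unit():
    return UnitConfig()


@pytest.fixture(scope="session")
def spont_events(default_unit):
    """60 s of spontaneous activity from the default unit (~5000 events)."""
    events, truth = simulate_unit(default_unit, Silence(60.0), seed=101)
    return events, truth


@pytest.fixture(scope="session")
def fra_events(default_unit):
    """Tagged FRA responses (20 x 10 grid, 5 repetitions)."""
    cfg = default_unit
    protocol = generate_fra_protocol(cfg.cf / 4, cfg.cf * 4, 0.0, 90.0,
                                     repetitions=5, seed=11)
    events, _ = simulate_unit(cfg, protocol, seed=12)
    return events, protocol


@pytest.fixture(scope="session")
def rgs_unit(default_unit):
    """One RGS response (12 s x 10 trials) with its stimulus and truth."""
    rgs = generate_rgs(default_unit.cf, 12.0, 0.010, seed=21, level=60.0)
    events, truth = simulate_unit(default_unit, rgs, n_trials=10, seed=22,
                                  level_db=60.0)
    return events, rgs, truth


@pytest.fixture(scope="session")
def rgs_population(default_unit):
    """20 seeded RGS units (10 trials x 12 s each) for removal contrasts."""
    units = []
    for u in range(20):
        rgs = generate_rgs(default_unit.cf, 12.0, 0.010, seed=500 + u,
                           level=60.0)
        events, _ = simulate_unit(default_unit, rgs, n_trials=10,
                                  seed=600 + u, level_db=60.0)
        units.append((events, 12.0))
    return units
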