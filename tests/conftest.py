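"""Shared fixtures: default parameters and cached season runs.

Season simulations are deterministic, so expensive runs are computed once
per session and shared read-only across tests.
"""

import pytest
from hypothesis import settings

import paddynsim as ps

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return ps.default_parameter_set()


@pytest.fixture(scope="session")
def config():
    return ps.default_simulation_config()


@pytest.fixture(scope="session")
def season_nsr0():
    """Default scenario: 3 t straw, 2:1:2 split, no inhibitor, 2019-like."""
    return ps.run_season(ps.ScenarioSpec(3.0, (2, 1, 2), False))


@pytest.fixture(scope="session")
def season_nsr0_ui():
    return ps.run_season(ps.ScenarioSpec(3.0, (2, 1, 2), True))


@pytest.fixture(scope="session")
def straw_sweep():
    """Seasons across the full straw range at the base split, UI off/on."""
    out = {}
    for straw in (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0):
        for ui in (False, True):
            out[(straw, ui)] = ps.run_season(
                ps.ScenarioSpec(straw, (2, 1, 2), ui))
    return out
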