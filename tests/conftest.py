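"""Shared fixtures: reference parameters, initial state, and reusable runs.

Heavy simulations are session-scoped so the suite runs them once; tests
must not mutate them (take copies instead).
"""

import pytest

import sbdyn


@pytest.fixture(scope="session")
def params() -> sbdyn.ParameterSet:
    return sbdyn.ParameterSet()


@pytest.fixture(scope="session")
def initial(params) -> sbdyn.ModelState:
    return sbdyn.build_initial_state(params)


@pytest.fixture(scope="session")
def weekly_grid7() -> sbdyn.TimeGrid:
    return sbdyn.TimeGrid(dt_days=7.0, horizon_years=7.0, storage_stride=1)


@pytest.fixture(scope="session")
def weekly_grid30() -> sbdyn.TimeGrid:
    return sbdyn.TimeGrid(dt_days=7.0, horizon_years=30.0, storage_stride=1)


@pytest.fixture(scope="session")
def baseline30(params, initial, weekly_grid30) -> sbdyn.Trajectory:
    return sbdyn.simulate(params, grid=weekly_grid30, initial=initial)


@pytest.fixture(scope="session")
def baseline30_indicators(baseline30) -> sbdyn.IndicatorSeries:
    return sbdyn.extract_indicators(baseline30)


@pytest.fixture(scope="session")
def fixture_cv0(params) -> sbdyn.FixtureBundle:
    return sbdyn.generate_fixture(cv=0.0, seed=0, params=params)

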