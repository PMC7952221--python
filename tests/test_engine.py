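"""Integrator, trajectory, and indicator-extraction tests."""

import datetime as dt

import numpy as np
import pytest

import sbdyn
from sbdyn.engine import (TimeGrid, Trajectory, conservation_residual,
                          euler_integrate)
from sbdyn.model_core import (ACCUMULATOR_SLICE, I_CUM_SD, I_D, ModelState,
                              N_STATE, ConfigurationError)
from sbdyn.scenarios import Scenario


class TestTimeGrid:
    def test_default_grid_matches_convention(self):
        g = TimeGrid()
        assert g.dt_days == pytest.approx(7.0 / 16.0)
        assert g.n_steps == 1565 * 16  # whole weeks x sixteenth-week steps

    def test_halved_step_doubles_step_count(self):
        assert TimeGrid(dt_days=0.4375 / 2).n_steps == 2 * TimeGrid().n_steps

    def test_invalid_dt_rejected(self):
        with pytest.raises(ConfigurationError):
            TimeGrid(dt_days=0.0)

    def test_calendar_conversion(self):
        g = TimeGrid()
        assert g.year_to_t(2021) == 10.0
        assert g.date_to_t(dt.date(2011, 1, 1)) == 0.0


class TestEulerIntegrate:
    def test_exponential_decay_oracle(self):
        # pure outflow k=0.2/y from 1000 over 5 years vs the closed form
        k = 0.2
        times, states, clips = euler_integrate(
            lambda y, t: -k * y, np.array([1000.0]),
            n_steps=5 * 52, dt_years=7.0 / 365.25)
        expected = 1000.0 * np.exp(-k * times[-1])
        assert states[-1, 0] == pytest.approx(expected, rel=5e-3)
        assert clips == 0

    def test_clipping_counts_negativity_events(self):
        # constant outflow from a nearly empty stock must clip at zero
        _, states, clips = euler_integrate(
            lambda y, t: np.array([-100.0]), np.array([1.0]),
            n_steps=10, dt_years=0.1)
        assert clips > 0
        assert states[-1, 0] == 0.0


class TestSimulate:
    def test_null_parameters_leave_state_unchanged(self, params, initial):
        zero = {n: 0.0 for n in params.names()
                if params[n].unit in ("1/y", "per 100,000/y", "elasticity",
                                      "consultations/y")
                or n.startswith("capacity0") or n == "birth_rate"}
        ps = params.with_values(zero, clip=True)
        grid = TimeGrid(dt_days=7.0, horizon_years=2.0, storage_stride=1)
        traj = sbdyn.simulate(ps, grid=grid, initial=initial)
        np.testing.assert_array_equal(traj.states[-1], initial.y)

    def test_bitwise_determinism(self, params, initial):
        grid = TimeGrid(dt_days=7.0, horizon_years=3.0, storage_stride=1)
        a = sbdyn.simulate(params, grid=grid, initial=initial)
        b = sbdyn.simulate(params, grid=grid, initial=initial)
        np.testing.assert_array_equal(a.states, b.states)

    def test_unit_multiplier_scenario_is_bitwise_baseline(self, params,
                                                          initial):
        grid = TimeGrid(dt_days=7.0, horizon_years=12.0, storage_stride=1)
        neutral = Scenario("neutral", "all multipliers one",
                           modifications={"ed_rate": 1.0,
                                          "dv_base_rate": 1.0})
        a = sbdyn.simulate(params, grid=grid, initial=initial)
        b = sbdyn.simulate(params, scenario=neutral, grid=grid,
                           initial=initial)
        np.testing.assert_array_equal(a.states, b.states)

    def test_accumulators_monotone(self, baseline30):
        acc = baseline30.states[:, ACCUMULATOR_SLICE]
        assert np.all(np.diff(acc, axis=0) >= -1e-9)

    def test_no_flow_limiting_at_reference_parameters(self, baseline30):
        assert baseline30.flow_limit_events == 0

    def test_every_stored_state_valid(self, baseline30):
        for row in baseline30.states[::52]:
            ModelState(row).validate(rtol=1e-6)

    def test_population_conservation(self, baseline30):
        assert conservation_residual(baseline30) < 1e-6


class TestIndicators:
    def test_rate_arithmetic_from_handmade_trajectory(self, params):
        # 80 deaths in one year over a constant 500,000 -> 16.0 per 100,000
        y0 = np.zeros(N_STATE)
        y0[I_D + 3] = 500_000.0  # adult band, low distress
        y1 = y0.copy()
        y1[I_CUM_SD + 2] = 80.0
        traj = Trajectory(np.array([0.0, 1.0]), np.vstack([y0, y1]),
                          TimeGrid(horizon_years=1.0), params, None)
        ind = sbdyn.extract_indicators(traj)
        assert ind.annual.loc[2011, "suicide_rate_total"] == pytest.approx(16.0)

    def test_zero_hazards_give_zero_event_indicators(self, params, initial):
        ps = params.with_values({"attempt_hazard_mod": 0.0,
                                 "attempt_hazard_high": 0.0})
        grid = TimeGrid(dt_days=7.0, horizon_years=3.0, storage_stride=1)
        ind = sbdyn.extract_indicators(
            sbdyn.simulate(ps, grid=grid, initial=initial))
        assert (ind.annual["suicide_rate_total"] == 0).all()
        assert (ind.annual["self_harm_rate_youth"] == 0).all()

    def test_cumulative_equals_sum_of_annual_events(self,
                                                    baseline30_indicators):
        ind = baseline30_indicators
        annual_sum = ind.annual.loc[2021:2040, "suicide_deaths"].sum()
        assert ind.cumulative["suicide_total"] == pytest.approx(
            annual_sum, rel=1e-6)

    def test_youth_share_of_cumulative_counts(self, baseline30_indicators):
        c = baseline30_indicators.cumulative
        assert 0 < c["suicide_youth"] < c["suicide_total"]
        assert 0 < c["self_harm_youth"] < c["self_harm_total"]

    def test_short_trajectory_raises(self, params, initial):
        grid = TimeGrid(dt_days=7.0, horizon_years=0.5, storage_stride=1)
        traj = sbdyn.simulate(params, grid=grid, initial=initial)
        with pytest.raises(IndexError):
            sbdyn.extract_indicators(traj)


class TestPercentReduction:
    def _series(self, counts):
        import pandas as pd
        return sbdyn.IndicatorSeries(pd.DataFrame(), dict(counts))

    def test_identity_and_arithmetic(self):
        base = self._series({"suicide_total": 1000.0})
        assert sbdyn.percent_reduction(
            base, self._series({"suicide_total": 1000.0}),
            "suicide_total") == 0.0
        assert sbdyn.percent_reduction(
            base, self._series({"suicide_total": 900.0}),
            "suicide_total") == pytest.approx(10.0)
        assert sbdyn.percent_reduction(
            base, self._series({"suicide_total": 1100.0}),
            "suicide_total") == pytest.approx(-10.0)

    def test_zero_baseline_is_an_error(self):
        base = self._series({"suicide_total": 0.0})
        with pytest.raises(ZeroDivisionError):
            sbdyn.percent_reduction(
                base, self._series({"suicide_total": 0.0}), "suicide_total")

    def test_unknown_outcome_rejected(self):
        base = self._series({"suicide_total": 10.0})
        with pytest.raises(KeyError):
            sbdyn.percent_reduction(base, base, "not_an_outcome")
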