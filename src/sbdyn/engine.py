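"""Fixed-step simulation over the 2011–2041 horizon and indicator extraction.

The integrator is explicit Euler at the system-dynamics convention of one
sixteenth of a week (0.4375 days), the step at which all model outputs are
calculated.  Calendar handling uses years of 365.25 days, with the horizon
anchored at 1 January 2011; the forecast window "2021–2041" is the half-open
interval [2021-01-01, 2041-01-01).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Callable, TYPE_CHECKING

import numpy as np
import pandas as pd

from .model_core import (
    ADULT_BANDS,
    ConfigurationError,
    DISTRESS_LEVELS,
    GP,
    DIS,
    InvalidStateError,
    I_CUM_BIRTH,
    I_CUM_DEATH,
    I_CUM_ED,
    I_CUM_MIG,
    I_CUM_PSY,
    I_CUM_SD,
    I_CUM_SH,
    ModelState,
    N_STATE,
    ParameterSet,
    SPEC,
    WAIT,
    _deriv,
    _modifiers,
)

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import Scenario

logger = logging.getLogger(__name__)

START_DATE = _dt.date(2011, 1, 1)
DAYS_PER_YEAR = 365.25
DEFAULT_DT_DAYS = 0.4375  # one sixteenth of a week

#: Cumulative 2021–2041 outcome names.
CUMULATIVE_OUTCOMES = ("self_harm_total", "self_harm_youth",
                       "suicide_total", "suicide_youth")


@dataclass(frozen=True)
class TimeGrid:
    """Simulation time grid: start date, step (days), horizon (years)."""

    start: _dt.date = START_DATE
    dt_days: float = DEFAULT_DT_DAYS
    horizon_years: float = 30.0
    storage_stride: int = 16  # store weekly at the default step

    def __post_init__(self):
        if self.dt_days <= 0:
            raise ConfigurationError("dt must be positive")
        if self.horizon_years <= 0:
            raise ConfigurationError("horizon must be positive")

    @property
    def dt_years(self) -> float:
        return self.dt_days / DAYS_PER_YEAR

    @property
    def n_steps(self) -> int:
        # whole weeks over the horizon, then whole steps per week
        n_weeks = round(self.horizon_years * DAYS_PER_YEAR / 7.0)
        return int(round(n_weeks * 7.0 / self.dt_days))

    def date_to_t(self, date: _dt.date) -> float:
        """Calendar date -> years since the grid start.

        Whole calendar years count as exactly 1.0 (so 1 January 2021 is
        t = 10.0); the within-year fraction uses 365.25-day years.
        """
        whole = date.year - self.start.year
        frac = ((date - _dt.date(date.year, 1, 1)).days
                - (self.start - _dt.date(self.start.year, 1, 1)).days)
        return whole + frac / DAYS_PER_YEAR

    def year_to_t(self, year: int) -> float:
        """1 January of ``year`` -> years since start."""
        return float(year - self.start.year)


@dataclass
class Trajectory:
    """Dense simulated states at the storage stride, plus run metadata."""

    times: np.ndarray                 # years since start, strictly increasing
    states: np.ndarray                # (n_stored, N_STATE)
    grid: TimeGrid
    params: ParameterSet
    scenario: "Scenario | None" = None
    flow_limit_events: int = 0        # steps on which negativity clipping fired

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise InvalidStateError("trajectory times must strictly increase")

    @property
    def final_state(self) -> ModelState:
        return ModelState(self.states[-1])

    def state_at(self, t: float) -> ModelState:
        """Linearly interpolated state at ``t`` years since start."""
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise IndexError(f"t={t} outside trajectory span")
        y = np.array([np.interp(t, self.times, self.states[:, i])
                      for i in range(N_STATE)])
        return ModelState(y)

    def interp(self, t: float) -> np.ndarray:
        i = int(np.searchsorted(self.times, t, side="right")) - 1
        i = min(max(i, 0), len(self.times) - 2)
        t0, t1 = self.times[i], self.times[i + 1]
        w = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
        w = min(max(w, 0.0), 1.0)
        return (1 - w) * self.states[i] + w * self.states[i + 1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (time, variable)."""
        rows = []
        for t, y in zip(self.times, self.states):
            for name, val in ModelState(y).as_dict().items():
                rows.append((t, name, val))
        return pd.DataFrame(rows, columns=["time_years", "variable", "value"])


def euler_integrate(f: Callable[[np.ndarray, float], np.ndarray],
                    y0: np.ndarray, n_steps: int, dt_years: float,
                    t0: float = 0.0, storage_stride: int = 1,
                    clip_negative: bool = True
                    ) -> tuple[np.ndarray, np.ndarray, int]:
    """Generic explicit-Euler loop.

    Returns ``(times, states, clip_events)``.  When ``clip_negative`` is
    set, any stock driven below zero within a step is floored at zero and
    the event counted (under the reference parameterisation at the default
    step this never fires; it is a guard for extreme parameter draws).
    """
    y = np.array(y0, dtype=float)
    n_stored = n_steps // storage_stride + 1
    if n_steps % storage_stride:
        n_stored += 1
    times = np.empty(n_stored)
    states = np.empty((n_stored, y.size))
    times[0] = t0
    states[0] = y
    k = 1
    clip_events = 0
    t = t0
    for step in range(1, n_steps + 1):
        y = y + dt_years * f(y, t)
        t = t0 + step * dt_years
        if clip_negative:
            neg = y < 0.0
            if neg.any():
                clip_events += 1
                y[neg] = 0.0
        if not np.all(np.isfinite(y)):
            bad = int(np.argmin(np.isfinite(y)))
            raise InvalidStateError(
                f"non-finite state at step {step} (t={t:.4f} y), index {bad}")
        if step % storage_stride == 0 or step == n_steps:
            times[k] = t
            states[k] = y
            k += 1
    return times[:k], states[:k], clip_events


def simulate(params: ParameterSet, scenario: "Scenario | None" = None,
             grid: TimeGrid | None = None,
             initial: ModelState | None = None) -> Trajectory:
    """Run the model over the grid, applying scenario modifications from the
    scenario's start date onward.  Bit-reproducible for identical inputs."""
    from .scenarios import Scenario  # local import to avoid a cycle

    if grid is None:
        grid = TimeGrid()
    if initial is None:
        raise ConfigurationError("an initial ModelState is required")
    initial.validate()
    if scenario is None:
        scenario = Scenario.baseline()
    p_base = params.compiled()
    start_t = grid.date_to_t(scenario.start)
    if scenario.modifications:
        p_post = scenario.apply(params, start_t + 1e-9).compiled()
    else:
        p_post = p_base
        start_t = float("inf")
    dt = grid.dt_years

    def f(y, t):
        return _deriv(y, t, p_post if t >= start_t else p_base)

    times, states, clips = euler_integrate(
        f, initial.y, grid.n_steps, dt, t0=0.0,
        storage_stride=grid.storage_stride)
    if clips:
        logger.warning("flow limiting activated on %d steps", clips)
    return Trajectory(times, states, grid, params, scenario, clips)


# --------------------------------------------------------------------------
# Indicator extraction
# --------------------------------------------------------------------------


@dataclass
class IndicatorSeries:
    """Annual indicator series plus cumulative 2021–2041 outcome counts.

    ``annual`` is indexed by calendar year; rates are per 100,000 mid-year
    population per year, prevalences are mid-year stock shares in percent.
    """

    annual: pd.DataFrame
    cumulative: dict = field(default_factory=dict)

    def series(self, name: str) -> pd.Series:
        if name not in self.annual.columns:
            raise KeyError(f"unknown indicator {name!r}")
        return self.annual[name]

    def to_frame(self) -> pd.DataFrame:
        df = self.annual.reset_index().melt(
            id_vars="year", var_name="variable", value_name="value")
        return df.sort_values(["variable", "year"]).reset_index(drop=True)


def extract_indicators(traj: Trajectory, grid: TimeGrid | None = None
                       ) -> IndicatorSeries:
    """Annual rates/prevalences and cumulative 2021–2041 counts.

    Annual event rates are (events in the calendar year) / (mid-year
    population) x 100,000; events come from differencing the cumulative
    accumulators at year boundaries (linearly interpolated between stored
    steps, which makes the result storage-stride independent).
    """
    if grid is None:
        grid = traj.grid
    # whole-week horizons can stop a day or two short of the last year
    # boundary; edge interpolation clamps, so allow that slack
    horizon = traj.times[-1]
    n_years = int(np.floor(horizon + 0.01))
    if n_years < 1:
        raise IndexError("trajectory shorter than one year")
    params = traj.params
    scenario = traj.scenario

    years = np.arange(grid.start.year, grid.start.year + n_years)
    rows = []
    cum_cols = [I_CUM_SH, I_CUM_SH + 1, I_CUM_SH + 2, I_CUM_SH + 3,
                I_CUM_SD, I_CUM_SD + 1, I_CUM_SD + 2, I_CUM_SD + 3,
                I_CUM_ED, I_CUM_PSY]
    for i, year in enumerate(years):
        y0 = traj.interp(float(i))
        y1 = traj.interp(float(i + 1))
        mid = ModelState(traj.interp(i + 0.5))
        ev = y1[cum_cols] - y0[cum_cols]
        sh = ev[0:4]
        sd = ev[4:8]
        pop = mid.population
        total = pop.sum()
        pop_15plus = pop[1:].sum()

        def _per(events, persons, scale):
            return events / persons * scale if persons > 0 else 0.0

        row = {
            "year": year,
            "population_total": total,
            "population_youth": pop[1],
            "suicide_rate_total": _per(sd.sum(), total, 1e5),
            "suicide_rate_youth": _per(sd[1], pop[1], 1e5),
            "self_harm_rate_total": _per(sh.sum(), total, 1e5),
            "self_harm_rate_youth": _per(sh[1], pop[1], 1e5),
            "suicide_deaths": sd.sum(),
            "self_harm_hospitalisations": sh.sum(),
            "ed_presentations": ev[8],
            "psych_hospitalisations": ev[9],
        }
        for bi, b in enumerate(ADULT_BANDS):
            for li, l in enumerate(DISTRESS_LEVELS):
                row[f"distress_{l}_prev_{b}"] = _per(
                    mid.distress[bi, li], pop[1 + bi], 100.0)
        row["unemployment_rate"] = mid.unemployment_rate() * 100.0
        row["unemployment_rate_youth"] = mid.unemployment_rate("youth") * 100.0
        row["homeless_per10k"] = _per(mid.homeless.sum(), total, 1e4)
        row["substance_prev"] = _per(mid.substance_misuse.sum(), pop_15plus, 100.0)
        # service-use measures at mid-year
        t_mid = i + 0.5
        eff = scenario.apply(params, t_mid) if scenario is not None else params
        pc = eff.compiled()
        mods = _modifiers(mid.y, pc)
        row["dv_rate"] = mods.dv_rate
        row["gp_consults"] = mid.care[:, GP].sum() * eff.value("gp_consult_freq")
        row["specialist_consults"] = (mid.care[:, SPEC].sum()
                                      * eff.value("specialist_consult_freq"))
        cap = pc.cap0 * (total / pc.init_population) * (1 + pc.cap_growth) ** t_mid
        wait_tot = mid.care[:, WAIT].sum()
        row["mean_wait_weeks"] = float(
            (pc.triage * (pc.triage * wait_tot / np.maximum(cap[:4], 1e-12))).sum())
        row["disengaged"] = mid.care[:, DIS].sum()
        rows.append(row)
    annual = pd.DataFrame(rows).set_index("year")

    cumulative: dict[str, float] = {}
    t_lo, t_hi = grid.year_to_t(2021), grid.year_to_t(2041)
    if horizon + 0.01 >= t_hi and t_lo >= -1e-9:
        a0 = traj.interp(t_lo)
        a1 = traj.interp(t_hi)
        d_sh = a1[I_CUM_SH:I_CUM_SH + 4] - a0[I_CUM_SH:I_CUM_SH + 4]
        d_sd = a1[I_CUM_SD:I_CUM_SD + 4] - a0[I_CUM_SD:I_CUM_SD + 4]
        cumulative = {
            "self_harm_total": float(d_sh.sum()),
            "self_harm_youth": float(d_sh[1]),
            "suicide_total": float(d_sd.sum()),
            "suicide_youth": float(d_sd[1]),
        }
    return IndicatorSeries(annual, cumulative)


def percent_reduction(baseline: IndicatorSeries, scenario: IndicatorSeries,
                      outcome: str) -> float:
    """100 x (baseline - scenario) / baseline for a cumulative outcome;
    negative values (harm) are permitted and reported as such."""
    if outcome not in CUMULATIVE_OUTCOMES:
        raise KeyError(f"unknown cumulative outcome {outcome!r}")
    b = baseline.cumulative[outcome]
    s = scenario.cumulative[outcome]
    if b == 0:
        raise ZeroDivisionError(f"baseline count for {outcome!r} is zero")
    return 100.0 * (b - s) / b


def conservation_residual(traj: Trajectory) -> float:
    """|Δ total population − (births + migration − deaths − suicides)|
    relative to the initial population (an integrator diagnostic)."""
    y0, y1 = traj.states[0], traj.states[-1]
    dpop = ModelState(y1).total_population - ModelState(y0).total_population
    flows = ((y1[I_CUM_BIRTH] - y0[I_CUM_BIRTH])
             + (y1[I_CUM_MIG] - y0[I_CUM_MIG])
             - (y1[I_CUM_DEATH] - y0[I_CUM_DEATH])
             - (y1[I_CUM_SD:I_CUM_SD + 4].sum()
                - y0[I_CUM_SD:I_CUM_SD + 4].sum()))
    return abs(dpop - flows) / ModelState(y0).total_population
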