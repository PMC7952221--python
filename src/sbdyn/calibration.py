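"""Constrained calibration of free parameters against observed annual series.

The objective is the sum over observed time series of the mean absolute
percent error (MAPE) between each series and the matching simulated annual
indicator, minimised with Powell's derivative-free direction-set method.
Bounds are handled by clamping the proposed vector into the bounds and
adding a logged quadratic penalty for the excursion, which keeps the
objective finite and derivative-free-friendly; optional jittered restarts
guard against poor local minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .engine import IndicatorSeries, TimeGrid, extract_indicators, simulate
from .model_core import ConfigurationError, ModelState, ParameterSet

logger = logging.getLogger(__name__)

#: Objective value returned when a simulation fails (optimizer-safe).
FAILURE_PENALTY = 1e6


@dataclass
class ObservedSeries:
    """One observed annual indicator series used by the MAPE objective."""

    name: str                  # must match an IndicatorSeries column
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ConfigurationError("years and values differ in length")
        bad = self.values == 0
        if bad.any():
            yr = int(self.years[np.argmax(bad)])
            raise ConfigurationError(
                f"series {self.name!r} has a zero observation in {yr}; "
                "MAPE requires nonzero observed values")


def mape(observed: ObservedSeries, simulated: np.ndarray) -> float:
    """Mean absolute percent error: (100/n) * sum |obs - sim| / obs."""
    sim = np.asarray(simulated, dtype=float)
    if sim.shape != observed.values.shape:
        raise ConfigurationError(
            f"simulated length {sim.size} != observed length "
            f"{observed.values.size} for {observed.name!r}")
    return float(100.0 * np.mean(np.abs(observed.values - sim) / observed.values))


@dataclass
class CalibrationProblem:
    """Free parameters, observed series, and optimizer settings."""

    free_names: list[str]
    observed: list[ObservedSeries]
    params: ParameterSet
    initial: ModelState
    grid: TimeGrid = field(default_factory=lambda: TimeGrid(
        dt_days=7.0, horizon_years=7.0, storage_stride=1))
    initial_guess: np.ndarray | None = None
    xtol: float = 1e-4
    ftol: float = 1e-6
    max_iterations: int = 60
    restarts: int = 0
    restart_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self):
        for n in self.free_names:
            p = self.params[n]  # raises on unknown names
            if not (np.isfinite(p.lower) and np.isfinite(p.upper)):
                raise ConfigurationError(f"non-finite bounds for {n!r}")
        if self.initial_guess is None:
            self.initial_guess = self.params.values(self.free_names)
        self.initial_guess = np.asarray(self.initial_guess, dtype=float)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [(self.params[n].lower, self.params[n].upper)
                for n in self.free_names]


def objective(param_vector: np.ndarray, problem: CalibrationProblem) -> float:
    """Summed per-series MAPE at a free-parameter vector.

    Out-of-bounds components are clamped with a quadratic penalty added;
    simulation failures return a large finite penalty.
    """
    x = np.asarray(param_vector, dtype=float)
    penalty = 0.0
    clamped = {}
    for n, xi, (lo, hi) in zip(problem.free_names, x, problem.bounds):
        ci = min(max(xi, lo), hi)
        if ci != xi:
            scale = max(abs(hi - lo), 1e-12)
            penalty += 100.0 * ((xi - ci) / scale) ** 2
            logger.debug("clamped %s: %g -> %g", n, xi, ci)
        clamped[n] = ci
    params = problem.params.with_values(clamped)
    try:
        traj = simulate(params, grid=problem.grid, initial=problem.initial)
        ind = extract_indicators(traj)
    except Exception as exc:  # simulation failure -> optimizer-safe penalty
        logger.warning("simulation failed during calibration: %s", exc)
        return FAILURE_PENALTY + penalty
    total = penalty
    for obs in problem.observed:
        sim = ind.series(obs.name).reindex(obs.years).to_numpy()
        if np.any(~np.isfinite(sim)):
            return FAILURE_PENALTY + penalty
        total += mape(obs, sim)
    return float(total)


@dataclass
class CalibrationResult:
    params: ParameterSet
    free_names: list[str]
    x: np.ndarray
    objective: float
    per_series_mape: dict[str, float]
    n_iterations: int
    n_evaluations: int
    converged: bool

    def report(self) -> pd.DataFrame:
        rows = [{"quantity": f"fitted:{n}", "value": v}
                for n, v in zip(self.free_names, self.x)]
        rows += [{"quantity": f"mape:{k}", "value": v}
                 for k, v in self.per_series_mape.items()]
        rows += [{"quantity": "objective", "value": self.objective},
                 {"quantity": "iterations", "value": self.n_iterations},
                 {"quantity": "evaluations", "value": self.n_evaluations},
                 {"quantity": "converged", "value": float(self.converged)}]
        return pd.DataFrame(rows)


def calibrate(problem: CalibrationProblem) -> CalibrationResult:
    """Powell direction-set search from the initial guess, with optional
    jittered restarts; never returns a vector worse than the initial guess."""
    if not problem.free_names:
        f0 = objective(np.array([]), problem)
        return CalibrationResult(problem.params.copy(), [], np.array([]), f0,
                                 _per_series(problem, {}), 0, 1, True)
    x0 = problem.initial_guess
    f0 = objective(x0, problem)
    if not np.isfinite(f0):
        raise ConfigurationError("objective non-finite at the initial guess")
    best_x, best_f = np.array(x0, dtype=float), f0
    n_iter = n_eval = 1
    converged = False
    rng = np.random.default_rng(problem.seed)
    starts = [x0]
    lo = np.array([b[0] for b in problem.bounds])
    hi = np.array([b[1] for b in problem.bounds])
    for _ in range(problem.restarts):
        jit = x0 * (1.0 + problem.restart_jitter * rng.standard_normal(x0.size))
        starts.append(np.clip(jit, lo, hi))
    for xs in starts:
        if np.all(lo == hi):  # fully constrained: nothing to search
            best_x, best_f = lo.copy(), objective(lo, problem)
            converged = True
            break
        res = minimize(objective, xs, args=(problem,), method="Powell",
                       bounds=problem.bounds,
                       options={"xtol": problem.xtol, "ftol": problem.ftol,
                                "maxiter": problem.max_iterations,
                                "maxfev": 200 * max(1, x0.size)})
        n_iter += int(res.nit)
        n_eval += int(res.nfev)
        if res.fun < best_f:
            best_x, best_f = np.clip(res.x, lo, hi), float(res.fun)
        converged = converged or bool(res.success)
    fitted = problem.params.with_values(
        dict(zip(problem.free_names, best_x)), source="calibrated")
    per_series = _per_series(problem, dict(zip(problem.free_names, best_x)))
    return CalibrationResult(fitted, list(problem.free_names), best_x, best_f,
                             per_series, n_iter, n_eval, converged)


def _per_series(problem: CalibrationProblem, values: dict) -> dict[str, float]:
    params = problem.params.with_values(values, clip=True)
    traj = simulate(params, grid=problem.grid, initial=problem.initial)
    ind = extract_indicators(traj)
    return {obs.name: mape(obs, ind.series(obs.name).reindex(obs.years).to_numpy())
            for obs in problem.observed}


def observed_to_csv(series_list: list[ObservedSeries], path) -> None:
    rows = [(s.name, int(y), float(v))
            for s in series_list for y, v in zip(s.years, s.values)]
    pd.DataFrame(rows, columns=["series", "year", "value"]).to_csv(
        path, index=False)


def observed_from_csv(path) -> list[ObservedSeries]:
    df = pd.read_csv(path)
    out = []
    for name, g in df.groupby("series", sort=True):
        g = g.sort_values("year")
        out.append(ObservedSeries(str(name), g["year"].to_numpy(),
                                  g["value"].to_numpy()))
    return out
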