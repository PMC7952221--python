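"""Latin-hypercube uncertainty analysis over intervention effects and
service-capacity growth.

Parameter sets are drawn from a uniform joint distribution spanning a ±span
band (default ±20%) around the default values, with the one-sample-per-bin
stratification that defines Latin hypercube sampling.  Each sampled set
replaces the defaults in *both* the baseline and the scenario run (paired
differencing), and the per-outcome percent reductions are summarised as the
mean and empirical 2.5th/97.5th percentiles.  The resulting 95% intervals
measure the impact of parameter uncertainty on the projections; they are
not confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .engine import (CUMULATIVE_OUTCOMES, TimeGrid, extract_indicators,
                     percent_reduction, simulate)
from .model_core import ConfigurationError, ModelState, ParameterSet
from .scenarios import Scenario, build_scenario

logger = logging.getLogger(__name__)

#: Reference sampled-parameter list: the six intervention direct effects and
#: the five per-service capacity growth rates.
DEFAULT_SENSITIVITY_PARAMS = (
    "effect_aftercare",
    "effect_connectedness",
    "effect_community_acute",
    "effect_crisis_response",
    "effect_coordinated_care",
    "effect_peer_support",
    "capacity_growth_gp",
    "capacity_growth_specialist",
    "capacity_growth_community",
    "capacity_growth_online",
    "capacity_growth_inpatient",
)


@dataclass
class LHSDesign:
    """A seeded Latin-hypercube design over ±span bands around defaults."""

    names: list[str]
    defaults: np.ndarray
    span: float
    seed: int
    samples: np.ndarray  # (n_samples, n_params), absolute parameter values

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.names)


def lhs_design(names, defaults, n: int = 100, span: float = 0.20,
               seed: int = 0) -> LHSDesign:
    """Draw ``n`` stratified samples per parameter from
    ``[default*(1-span), default*(1+span)]``.

    Each parameter's marginal samples place exactly one draw in each of the
    ``n`` equal-width bins (uniform within-bin placement).
    """
    names = list(names)
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate parameter names in design")
    defaults = np.asarray(defaults, dtype=float)
    if len(names) != defaults.size:
        raise ConfigurationError("names and defaults differ in length")
    if n < 2:
        raise ConfigurationError("n must be at least 2")
    if not (0 < span < 1):
        raise ConfigurationError("span must be in (0, 1)")
    if np.any(defaults <= 0):
        raise ConfigurationError("defaults must be positive")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    lo = defaults * (1.0 - span)
    hi = defaults * (1.0 + span)
    samples = qmc.scale(unit, lo, hi)
    return LHSDesign(names, defaults, span, seed, samples)


def design_from_params(params: ParameterSet,
                       names=DEFAULT_SENSITIVITY_PARAMS,
                       n: int = 100, span: float = 0.20,
                       seed: int = 0) -> LHSDesign:
    return lhs_design(names, params.values(list(names)), n=n, span=span,
                      seed=seed)


@dataclass
class SensitivitySummary:
    """Per (scenario, outcome): mean % reduction, 95% interval, and the full
    sample distribution; cases-prevented evaluated at the default values."""

    table: pd.DataFrame               # scenario, outcome, mean, lo, hi, ...
    distributions: dict = field(default_factory=dict)  # (scn, outcome) -> array
    n_failed: int = 0

    def row(self, scenario_id: str, outcome: str) -> pd.Series:
        m = self.table[(self.table.scenario == scenario_id)
                       & (self.table.outcome == outcome)]
        if m.empty:
            raise KeyError((scenario_id, outcome))
        return m.iloc[0]


def _reductions(params: ParameterSet, scenario: Scenario, grid: TimeGrid,
                initial: ModelState) -> dict[str, float]:
    base = extract_indicators(simulate(params, grid=grid, initial=initial))
    scn = extract_indicators(simulate(params, scenario=scenario, grid=grid,
                                      initial=initial))
    out = {}
    for oc in CUMULATIVE_OUTCOMES:
        out[oc] = percent_reduction(base, scn, oc)
        out[f"baseline_{oc}"] = base.cumulative[oc]
        out[f"scenario_{oc}"] = scn.cumulative[oc]
    return out


def run_sensitivity(scenario_ids, design: LHSDesign, params: ParameterSet,
                    grid: TimeGrid, initial: ModelState) -> SensitivitySummary:
    """Paired baseline/scenario runs for every design row.

    Percentiles are the empirical quantiles with linear interpolation
    (``numpy.percentile``, default scheme).  Rows whose simulation fails are
    excluded and counted; more than 10% failures is a hard error.
    """
    scenarios = {sid: build_scenario(sid, params) for sid in scenario_ids}
    rows: dict[str, list[dict]] = {sid: [] for sid in scenarios}
    n_failed = 0
    for r in range(design.n_samples):
        sampled = dict(zip(design.names, design.samples[r]))
        try:
            p_r = params.with_values(sampled, clip=True)
            # intervention multipliers derive from effect sizes: rebuild
            scn_r = {sid: build_scenario(sid, p_r) for sid in scenarios}
            for sid in scenarios:
                rows[sid].append(_reductions(p_r, scn_r[sid], grid, initial))
        except Exception as exc:
            n_failed += 1
            logger.warning("sensitivity row %d failed: %s", r, exc)
    if n_failed > 0.10 * design.n_samples:
        raise RuntimeError(
            f"{n_failed}/{design.n_samples} sensitivity rows failed")

    default_scn = {sid: build_scenario(sid, params) for sid in scenarios}
    out_rows = []
    distributions = {}
    for sid in scenarios:
        at_default = _reductions(params, default_scn[sid], grid, initial)
        for oc in CUMULATIVE_OUTCOMES:
            vals = np.array([row[oc] for row in rows[sid]])
            distributions[(sid, oc)] = vals
            prevented = at_default[f"baseline_{oc}"] - at_default[f"scenario_{oc}"]
            out_rows.append({
                "scenario": sid,
                "outcome": oc,
                "mean_pct_reduction": float(vals.mean()),
                "pct_2_5": float(np.percentile(vals, 2.5)),
                "pct_97_5": float(np.percentile(vals, 97.5)),
                "baseline_count": float(at_default[f"baseline_{oc}"]),
                "scenario_count": float(at_default[f"scenario_{oc}"]),
                "cases_prevented": int(round(prevented)),
                "pct_reduction_at_default": float(at_default[oc]),
                "n_samples": int(vals.size),
            })
    return SensitivitySummary(pd.DataFrame(out_rows), distributions, n_failed)
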