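"""Synthetic observed series and initial state for a regional catchment.

The study region's datasets are confidential; this module generates
*synthetic* annual 2011–2017 observation series from a known ground-truth
parameterisation whose simulated trajectory tracks the published regional
statistics (population, suicide rate, unemployment, domestic violence,
homelessness, youth share).  Calibration and every downstream stage can
therefore be exercised and tested without any external download, with the
truth available for parameter-recovery checks.  The fixtures are aggregate
series only and bear no resemblance to actual unit-record data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .calibration import ObservedSeries
from .engine import TimeGrid, extract_indicators, simulate
from .model_core import (ADULT_BANDS, I_C, I_CR, I_D, I_EMP, I_HML, I_SUB,
                         I_UNEMP, ModelState, N_STATE, ParameterSet)


@dataclass(frozen=True)
class RegionalProfile:
    """Published regional statistics anchoring the synthetic fixtures.

    The LGA-level extremes (unemployment, DV, homelessness) are upper
    anchors for region-wide values, not region-wide targets.
    """

    population_2016: float = 502_524.0
    youth_share_pct: float = 10.4          # of population, mid-2016
    older_share_pct: float = 20.4          # 65+
    suicide_rate_2006: float = 7.9         # per 100,000/y
    suicide_rate_2017: float = 16.6        # per 100,000/y
    unemployment_max_pct: float = 9.7      # LGA maximum (national 5.9)
    dv_rate_max: float = 757.1             # incidents per 100,000/y, LGA max
    homeless_max_per10k: float = 57.5      # LGA maximum
    child_at_risk_per1000: float = 79.7    # children 0-17 at risk of harm
    out_of_home_care_per1000: float = 16.3


def build_regional_profile() -> RegionalProfile:
    """The published anchors; single source of truth for fixture targets."""
    return RegionalProfile()


# 2011 composition used to assemble the initial state (reference defaults;
# band shares chosen so the 2016 simulated population and youth/older shares
# land on the profile anchors)
_BAND_SHARES = {"child": 0.170, "youth": 0.108, "adult": 0.524, "older": 0.198}
_CHILD_RISK_SHARES = (0.798, 0.121, 0.081)
_DISTRESS_SHARES = {        # low / moderate / high
    "youth": (0.62, 0.23, 0.15),
    "adult": (0.68, 0.22, 0.10),
    "older": (0.76, 0.17, 0.07),
}
_CARE_SHARES = (0.615, 0.021, 0.160, 0.045, 0.055, 0.020,
                0.002, 0.012, 0.015, 0.055)      # sums to 1
_UNEMPLOYMENT_2011 = {"youth": 0.121, "adult": 0.059}
_HOMELESS_SHARE = {"youth": 0.0074, "adult": 0.0045, "older": 0.0025}
_SUBSTANCE_SHARE = {"youth": 0.091, "adult": 0.048, "older": 0.008}

#: Fixture observation series (indicator names) emitted for calibration.
FIXTURE_SERIES = (
    "suicide_rate_total",
    "suicide_rate_youth",
    "self_harm_rate_total",
    "self_harm_rate_youth",
    "distress_high_prev_adult",
    "unemployment_rate",
    "dv_rate",
    "homeless_per10k",
    "ed_presentations",
    "psych_hospitalisations",
    "gp_consults",
)


def build_initial_state(params: ParameterSet | None = None) -> ModelState:
    """Assemble the 1 January 2011 state from the regional composition."""
    if params is None:
        params = ParameterSet()
    pop0 = params.value("init_population")
    y = np.zeros(N_STATE)
    y[I_CR:I_CR + 3] = pop0 * _BAND_SHARES["child"] * np.array(_CHILD_RISK_SHARES)
    care = np.array(_CARE_SHARES)
    for bi, b in enumerate(ADULT_BANDS):
        pb = pop0 * _BAND_SHARES[b]
        shares = np.array(_DISTRESS_SHARES[b])
        y[I_D + 3 * bi:I_D + 3 * bi + 3] = pb * shares
        pool = pb * (shares[1] + shares[2])
        y[I_C + 10 * bi:I_C + 10 * bi + 10] = pool * care
    for wi, b in enumerate(("youth", "adult")):
        pb = pop0 * _BAND_SHARES[b]
        lf = pb * params.value(f"participation_{b}")
        u = _UNEMPLOYMENT_2011[b]
        y[I_EMP + wi] = lf * (1.0 - u)
        y[I_UNEMP + wi] = lf * u
    for bi, b in enumerate(ADULT_BANDS):
        pb = pop0 * _BAND_SHARES[b]
        y[I_HML + bi] = pb * _HOMELESS_SHARE[b]
        y[I_SUB + bi] = pb * _SUBSTANCE_SHARE[b]
    state = ModelState(y)
    state.validate()
    return state


class AnchorError(RuntimeError):
    """The truth simulation strays too far from a profile anchor."""


@dataclass
class FixtureBundle:
    """Truth parameters, initial state, and (noisy) observed 2011–2017 series."""

    truth: ParameterSet
    initial: ModelState
    observed: list[ObservedSeries]
    cv: float
    seed: int
    grid: TimeGrid
    truth_indicators: object = None   # IndicatorSeries of the truth run

    def observed_by_name(self) -> dict[str, ObservedSeries]:
        return {s.name: s for s in self.observed}

    def manifest(self) -> dict:
        h = hashlib.sha256(
            json.dumps({n: self.truth.value(n) for n in self.truth.names()},
                       sort_keys=True).encode()).hexdigest()
        return {"seed": self.seed, "cv": self.cv, "truth_hash": h,
                "dt_days": self.grid.dt_days,
                "series": [s.name for s in self.observed]}


def generate_fixture(profile: RegionalProfile | None = None, cv: float = 0.05,
                     seed: int = 0, params: ParameterSet | None = None,
                     grid: TimeGrid | None = None,
                     series: tuple[str, ...] = FIXTURE_SERIES,
                     check_anchors: bool = True) -> FixtureBundle:
    """Simulate the truth parameterisation 2011–2017 and emit noisy annual
    observation series.

    Noise is multiplicative lognormal with coefficient of variation ``cv``
    (rates are positive and measurement error plausibly proportional);
    ``cv=0`` reproduces the truth indicators exactly.  Raises
    :class:`AnchorError` if the truth run is more than 25% off any regional
    anchor.
    """
    if profile is None:
        profile = build_regional_profile()
    if cv < 0:
        raise ValueError("cv must be non-negative")
    truth = (params or ParameterSet()).copy()
    if grid is None:
        grid = TimeGrid(dt_days=7.0, horizon_years=7.0, storage_stride=1)
    initial = build_initial_state(truth)
    traj = simulate(truth, grid=grid, initial=initial)
    ind = extract_indicators(traj)

    if check_anchors:
        _check_anchors(ind, profile, traj, grid)

    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log(1.0 + cv ** 2)))
    observed = []
    for name in series:
        s = ind.series(name)
        years = s.index.to_numpy()
        vals = s.to_numpy().astype(float)
        if cv > 0:
            noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                                  size=vals.size)
            vals = vals * noise
        observed.append(ObservedSeries(name, years, vals))
    return FixtureBundle(truth, initial, observed, cv, seed, grid, ind)


def _check_anchors(ind, profile: RegionalProfile, traj, grid: TimeGrid,
                   tol: float = 0.25) -> None:
    problems = []

    def check(label, value, target):
        if abs(value - target) > tol * target:
            problems.append(f"{label}: simulated {value:.3g} vs anchor "
                            f"{target:.3g} (> {tol:.0%} off)")

    pop_2016 = ind.annual.loc[2016, "population_total"]
    check("population 2016", pop_2016, profile.population_2016)
    youth_share = (ind.annual.loc[2016, "population_youth"] / pop_2016) * 100
    check("youth share 2016 (%)", youth_share, profile.youth_share_pct)
    check("suicide rate 2017", ind.annual.loc[2017, "suicide_rate_total"],
          profile.suicide_rate_2017)
    # LGA extremes bound the region-wide values from above
    u = ind.annual["unemployment_rate"].iloc[-1]
    if u > profile.unemployment_max_pct:
        problems.append(f"unemployment {u:.1f}% above the LGA maximum")
    dv = ind.annual["dv_rate"].iloc[-1]
    if dv > profile.dv_rate_max:
        problems.append(f"DV rate {dv:.0f} above the LGA maximum")
    hml = ind.annual["homeless_per10k"].iloc[-1]
    if hml > profile.homeless_max_per10k:
        problems.append(f"homelessness {hml:.1f}/10k above the LGA maximum")
    if problems:
        raise AnchorError("; ".join(problems))
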