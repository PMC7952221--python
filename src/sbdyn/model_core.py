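"""Stock-flow structure of the regional suicidal-behaviour model.

The model couples five components over a regional population catchment:

1. **Population** — four age bands (0–14, 15–24, 25–64, 65+) with births,
   net migration, ageing, and background mortality.
2. **Psychological distress** — within each band 15+, people occupy one of
   three Kessler-10 strata: low (K10 10–15), moderate (K10 16–21), or
   high/very-high (K10 22–50), with onset, escalation, and recovery flows.
3. **Social determinants** — unemployment, homelessness, substance misuse
   (stocks) and domestic-violence incidence (an auxiliary rate), which
   modulate distress incidence and each other through multiplicative
   elasticity couplings.
4. **Mental health services** — distressed people traverse a care pathway
   (waiting, GP, specialist, community, online, inpatient, post-discharge,
   post-attempt, disengaged) with capacity-limited intake and
   waiting-time-sensitive disengagement.  Care states carry recovery-rate
   and attempt-hazard multipliers.
5. **Suicidal behaviour** — attempt events arise from the distressed pool at
   level- and care-state-dependent hazards; a case-fatality fraction of
   attempts are suicide deaths, the nonfatal remainder are self-harm
   hospitalisations (the proxy used for attempts throughout).

Children (0–14) carry *risk of developing a mental disorder* (low / moderate
/ high) rather than K10 distress; risk maps to the initial distress
distribution when children age into the youth band, which is the channel
through which childhood-adversity interventions act.

All flows are evaluated by :func:`derivatives` as a pure function of the
state vector, a :class:`ParameterSet`, and time.  The state is a flat
``numpy`` vector; :class:`ModelState` provides named views onto it.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from types import SimpleNamespace
from typing import Iterable, Mapping

import numpy as np
import yaml

# --------------------------------------------------------------------------
# Age bands, distress levels, care states
# --------------------------------------------------------------------------

BANDS = ("child", "youth", "adult", "older")
#: Band widths in years; the open-ended 65+ band uses a 20-year expected
#: residence so that its ageing-out flow doubles as death bookkeeping.
BAND_WIDTHS = {"child": 15.0, "youth": 10.0, "adult": 40.0, "older": 20.0}

DISTRESS_LEVELS = ("low", "moderate", "high")
#: K10 score intervals for each distress stratum (inclusive).
K10_RANGES = {"low": (10, 15), "moderate": (16, 21), "high": (22, 50)}

CHILD_RISK_LEVELS = ("low", "moderate", "high")

CARE_STATES = (
    "not_in_care",
    "waiting",
    "gp_care",
    "specialist_care",
    "community_care",
    "online_care",
    "inpatient",
    "post_discharge",
    "post_attempt",
    "disengaged",
)
N_CARE = len(CARE_STATES)
# handy indices
NIC, WAIT, GP, SPEC, COMM, ONL, INPT, PDIS, PATT, DIS = range(N_CARE)

SERVICES = ("gp", "specialist", "community", "online", "inpatient")
#: Ambulatory services fed from the shared waiting pool, in triage order.
AMBULATORY = ("gp", "specialist", "community", "online")
_SVC_CARE_STATE = (GP, SPEC, COMM, ONL)

#: Bands that carry distress / care / determinant stocks (everything but child).
ADULT_BANDS = ("youth", "adult", "older")
#: Bands participating in employment flows.
WORKING_BANDS = ("youth", "adult")

WEEKS_PER_YEAR = 365.25 / 7.0

# --------------------------------------------------------------------------
# State vector layout
# --------------------------------------------------------------------------
# child risk (3) | distress (3 bands x 3 levels) | care (3 bands x 10 states)
# | employed (2) | unemployed (2) | homeless (3) | substance (3)
# | cum self-harm (4 bands) | cum suicide (4 bands) | cum ED | cum psych hosp
# | cum births | cum net migration | cum background deaths

I_CR = 0
I_D = 3
I_C = 12
I_EMP = 42
I_UNEMP = 44
I_HML = 46
I_SUB = 49
I_CUM_SH = 52
I_CUM_SD = 56
I_CUM_ED = 60
I_CUM_PSY = 61
I_CUM_BIRTH = 62
I_CUM_MIG = 63
I_CUM_DEATH = 64
N_STATE = 65

#: Indices of cumulative accumulators (non-decreasing along trajectories,
#: exempt from the "partition" invariants).
ACCUMULATOR_SLICE = slice(I_CUM_SH, N_STATE)

#: Per-band ageing-out rates (1/width); the older band's ageing-out is death.
AGE_OUT = np.array([1.0 / BAND_WIDTHS[b] for b in BANDS])

EPS_MODIFIER = 0.01  # floor for elasticity multipliers
_TINY = 1e-12


class InvalidStateError(ValueError):
    """A state vector violates a structural invariant (negative/non-finite)."""


class ConfigurationError(ValueError):
    """A parameter or configuration problem (missing name, bad bounds...)."""


# --------------------------------------------------------------------------
# ModelState
# --------------------------------------------------------------------------


class ModelState:
    """Named view over the flat state vector at one instant.

    The underlying storage is ``self.y`` (length :data:`N_STATE`); all
    accessors are views or cheap reductions over it.
    """

    __slots__ = ("y",)

    def __init__(self, y: np.ndarray | None = None):
        if y is None:
            y = np.zeros(N_STATE)
        y = np.asarray(y, dtype=float)
        if y.shape != (N_STATE,):
            raise InvalidStateError(f"state vector must have length {N_STATE}")
        self.y = y

    # ---- partition views -------------------------------------------------
    @property
    def child_risk(self) -> np.ndarray:
        """Children by risk level (low, moderate, high)."""
        return self.y[I_CR:I_CR + 3]

    @property
    def distress(self) -> np.ndarray:
        """Persons by (band ∈ youth/adult/older, distress level), shape (3, 3)."""
        return self.y[I_D:I_D + 9].reshape(3, 3)

    @property
    def care(self) -> np.ndarray:
        """Distressed persons by (band, care state), shape (3, 10)."""
        return self.y[I_C:I_C + 30].reshape(3, N_CARE)

    @property
    def employed(self) -> np.ndarray:
        return self.y[I_EMP:I_EMP + 2]

    @property
    def unemployed(self) -> np.ndarray:
        return self.y[I_UNEMP:I_UNEMP + 2]

    @property
    def homeless(self) -> np.ndarray:
        return self.y[I_HML:I_HML + 3]

    @property
    def substance_misuse(self) -> np.ndarray:
        return self.y[I_SUB:I_SUB + 3]

    @property
    def cum_self_harm_hosp(self) -> np.ndarray:
        return self.y[I_CUM_SH:I_CUM_SH + 4]

    @property
    def cum_suicide_deaths(self) -> np.ndarray:
        return self.y[I_CUM_SD:I_CUM_SD + 4]

    @property
    def cum_ed_presentations(self) -> float:
        return float(self.y[I_CUM_ED])

    @property
    def cum_psych_hospitalisations(self) -> float:
        return float(self.y[I_CUM_PSY])

    # ---- derived aggregates ---------------------------------------------
    @property
    def population(self) -> np.ndarray:
        """Population per band (child, youth, adult, older), derived from
        the partitions so the distress-partition invariant holds exactly."""
        return np.array([
            self.child_risk.sum(),
            *self.distress.sum(axis=1),
        ])

    @property
    def total_population(self) -> float:
        return float(self.population.sum())

    def unemployment_rate(self, band: str | None = None) -> float:
        """Unemployed / labour force, per working band or pooled."""
        if band is None:
            lf = self.employed.sum() + self.unemployed.sum()
            return float(self.unemployed.sum() / lf) if lf > 0 else 0.0
        i = WORKING_BANDS.index(band)
        lf = self.employed[i] + self.unemployed[i]
        return float(self.unemployed[i] / lf) if lf > 0 else 0.0

    def copy(self) -> "ModelState":
        return ModelState(self.y.copy())

    # ---- validation ------------------------------------------------------
    def validate(self, rtol: float = 1e-6) -> None:
        """Raise :class:`InvalidStateError` on any violated invariant."""
        y = self.y
        if not np.all(np.isfinite(y)):
            raise InvalidStateError("non-finite state values")
        if np.any(y < -rtol * max(1.0, self.total_population)):
            i = int(np.argmin(y))
            raise InvalidStateError(f"negative stock at index {i}: {y[i]}")
        pool = self.distress[:, 1] + self.distress[:, 2]
        care_pool = self.care.sum(axis=1)
        scale = max(1.0, self.total_population)
        if np.any(np.abs(pool - care_pool) > rtol * scale):
            raise InvalidStateError(
                "care partition does not sum to the distressed pool: "
                f"{care_pool} vs {pool}")
        lf = self.employed + self.unemployed
        pop_work = self.population[1:3]
        if np.any(lf > pop_work * (1 + rtol) + rtol):
            raise InvalidStateError("labour force exceeds band population")

    def as_dict(self) -> dict:
        """Flat mapping of named stocks (for export/debugging)."""
        out: dict[str, float] = {}
        for i, r in enumerate(CHILD_RISK_LEVELS):
            out[f"child_risk[{r}]"] = float(self.child_risk[i])
        for bi, b in enumerate(ADULT_BANDS):
            for li, l in enumerate(DISTRESS_LEVELS):
                out[f"distress[{b},{l}]"] = float(self.distress[bi, li])
            for si, s in enumerate(CARE_STATES):
                out[f"care[{b},{s}]"] = float(self.care[bi, si])
        for i, b in enumerate(WORKING_BANDS):
            out[f"employed[{b}]"] = float(self.employed[i])
            out[f"unemployed[{b}]"] = float(self.unemployed[i])
        for i, b in enumerate(ADULT_BANDS):
            out[f"homeless[{b}]"] = float(self.homeless[i])
            out[f"substance_misuse[{b}]"] = float(self.substance_misuse[i])
        for i, b in enumerate(BANDS):
            out[f"cum_self_harm_hosp[{b}]"] = float(self.cum_self_harm_hosp[i])
            out[f"cum_suicide_deaths[{b}]"] = float(self.cum_suicide_deaths[i])
        out["cum_ed_presentations"] = self.cum_ed_presentations
        out["cum_psych_hospitalisations"] = self.cum_psych_hospitalisations
        return out


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------


@dataclass
class Param:
    """One named scalar parameter with unit, bounds, and provenance."""

    value: float
    unit: str
    lower: float
    upper: float
    calibrate: bool = False
    source: str = "reference-default"

    def __post_init__(self):
        if not (self.lower <= self.value <= self.upper):
            raise ConfigurationError(
                f"value {self.value} outside bounds [{self.lower}, {self.upper}]")


def _p(value, unit, lower, upper, calibrate=False):
    return (value, unit, lower, upper, calibrate)


# name -> (value, unit, lower, upper, calibrate)
# Defaults are a reference parameterisation chosen so the uncalibrated model
# is consistent with the regional statistics the synthetic-data profile
# encodes; every default is replaceable from a config file.
_PARAM_DEFS: dict[str, tuple] = {
    # demography
    "init_population": _p(490_400, "persons", 3e5, 7e5),
    "ageing_rate_child": _p(1.0 / 15.0, "1/y", 0.0, 1.0),
    "ageing_rate_youth": _p(1.0 / 10.0, "1/y", 0.0, 1.0),
    "ageing_rate_adult": _p(1.0 / 40.0, "1/y", 0.0, 1.0),
    "ageing_rate_older": _p(1.0 / 20.0, "1/y", 0.0, 1.0),
    "birth_rate": _p(0.0105, "1/y", 0.0, 0.03),
    "migration_rate_child": _p(0.004, "1/y", -0.05, 0.05),
    "migration_rate_youth": _p(0.002, "1/y", -0.05, 0.05),
    "migration_rate_adult": _p(0.006, "1/y", -0.05, 0.05),
    "migration_rate_older": _p(0.012, "1/y", -0.05, 0.05),
    "mortality_child": _p(0.0002, "1/y", 0.0, 0.01),
    "mortality_youth": _p(0.0004, "1/y", 0.0, 0.01),
    "mortality_adult": _p(0.003, "1/y", 0.0, 0.02),
    "mortality_older": _p(0.002, "1/y", 0.0, 0.05),
    # child mental-disorder risk
    "child_risk_onset": _p(0.050, "1/y", 0.0, 0.3, True),
    "child_risk_escalation": _p(0.080, "1/y", 0.0, 0.5, True),
    "child_risk_recovery_mod": _p(0.25, "1/y", 0.0, 1.0),
    "child_risk_recovery_high": _p(0.12, "1/y", 0.0, 1.0),
    # risk -> initial youth distress mapping (low-distress share is remainder)
    "riskmap_low_mod": _p(0.10, "fraction", 0.0, 1.0),
    "riskmap_low_high": _p(0.02, "fraction", 0.0, 1.0),
    "riskmap_mod_mod": _p(0.38, "fraction", 0.0, 1.0),
    "riskmap_mod_high": _p(0.20, "fraction", 0.0, 1.0),
    "riskmap_high_mod": _p(0.35, "fraction", 0.0, 1.0),
    "riskmap_high_high": _p(0.55, "fraction", 0.0, 1.0),
    # psychological distress transitions
    "distress_onset_youth": _p(0.10, "1/y", 0.0, 2.0, True),
    "distress_onset_adult": _p(0.20, "1/y", 0.0, 2.0, True),
    "distress_onset_older": _p(0.14, "1/y", 0.0, 2.0, True),
    "distress_escalation_youth": _p(0.20, "1/y", 0.0, 3.0, True),
    "distress_escalation_adult": _p(0.35, "1/y", 0.0, 3.0, True),
    "distress_escalation_older": _p(0.30, "1/y", 0.0, 3.0, True),
    "distress_recovery_mod_youth": _p(0.28, "1/y", 0.0, 4.0, True),
    "distress_recovery_mod_adult": _p(0.62, "1/y", 0.0, 4.0, True),
    "distress_recovery_mod_older": _p(0.63, "1/y", 0.0, 4.0, True),
    "distress_recovery_high_youth": _p(0.30, "1/y", 0.0, 4.0, True),
    "distress_recovery_high_adult": _p(0.75, "1/y", 0.0, 4.0, True),
    "distress_recovery_high_older": _p(0.72, "1/y", 0.0, 4.0, True),
    # employment
    "participation_youth": _p(0.67, "fraction", 0.0, 1.0),
    "participation_adult": _p(0.78, "fraction", 0.0, 1.0),
    "job_loss_rate_youth": _p(0.055, "1/y", 0.0, 1.0, True),
    "job_loss_rate_adult": _p(0.028, "1/y", 0.0, 1.0, True),
    "job_finding_rate_youth": _p(0.40, "1/y", 0.0, 5.0, True),
    "job_finding_rate_adult": _p(0.45, "1/y", 0.0, 5.0, True),
    # homelessness
    "homeless_entry_youth": _p(0.0015, "1/y", 0.0, 0.05, True),
    "homeless_entry_adult": _p(0.0009, "1/y", 0.0, 0.05, True),
    "homeless_entry_older": _p(0.0005, "1/y", 0.0, 0.05, True),
    "homeless_exit_youth": _p(0.20, "1/y", 0.0, 2.0),
    "homeless_exit_adult": _p(0.20, "1/y", 0.0, 2.0),
    "homeless_exit_older": _p(0.20, "1/y", 0.0, 2.0),
    # substance misuse
    "substance_onset_youth": _p(0.012, "1/y", 0.0, 0.2, True),
    "substance_onset_adult": _p(0.006, "1/y", 0.0, 0.2, True),
    "substance_onset_older": _p(0.001, "1/y", 0.0, 0.2, True),
    "substance_remission": _p(0.12, "1/y", 0.0, 2.0),
    # domestic violence (auxiliary incidence rate)
    "dv_base_rate": _p(650.0, "per 100,000/y", 0.0, 2000.0, True),
    # coupling elasticities
    "beta_unemployment_distress": _p(0.10, "elasticity", 0.0, 2.0, True),
    "beta_unemployment_dv": _p(0.25, "elasticity", 0.0, 2.0, True),
    "beta_unemployment_homeless": _p(0.30, "elasticity", 0.0, 2.0, True),
    "beta_dv_distress": _p(0.08, "elasticity", 0.0, 2.0, True),
    "beta_homeless_distress": _p(0.10, "elasticity", 0.0, 2.0, True),
    "beta_distress_substance": _p(0.30, "elasticity", 0.0, 2.0, True),
    "beta_substance_dv": _p(0.20, "elasticity", 0.0, 2.0, True),
    "beta_substance_attempt": _p(0.15, "elasticity", 0.0, 2.0, True),
    "beta_distress_childrisk": _p(0.25, "elasticity", 0.0, 2.0, True),
    "beta_substance_childrisk": _p(0.20, "elasticity", 0.0, 2.0, True),
    "beta_dv_childrisk": _p(0.25, "elasticity", 0.0, 2.0, True),
    # reference driver levels (multipliers are 1 when drivers sit here)
    "ref_unemployment_youth": _p(0.121, "fraction", 0.01, 0.5),
    "ref_unemployment_adult": _p(0.059, "fraction", 0.01, 0.5),
    "ref_unemployment_total": _p(0.068, "fraction", 0.01, 0.5),
    "ref_dv_rate": _p(650.0, "per 100,000/y", 1.0, 2000.0),
    "ref_homeless_per10k": _p(38.0, "per 10,000", 0.1, 500.0),
    "ref_high_distress_prev": _p(0.100, "fraction", 0.005, 0.5),
    "ref_substance_prev": _p(0.044, "fraction", 0.005, 0.5),
    # services
    "care_seeking_rate": _p(0.90, "1/y", 0.0, 5.0, True),
    "intake_rate": _p(26.0, "1/y", 1.0, 100.0),
    "triage_gp": _p(0.55, "fraction", 0.0, 1.0),
    "triage_specialist": _p(0.15, "fraction", 0.0, 1.0),
    "triage_community": _p(0.20, "fraction", 0.0, 1.0),
    "triage_online": _p(0.10, "fraction", 0.0, 1.0),
    "completion_gp": _p(1.4, "1/y", 0.0, 12.0),
    "completion_specialist": _p(1.0, "1/y", 0.0, 12.0),
    "completion_community": _p(1.1, "1/y", 0.0, 12.0),
    "completion_online": _p(1.8, "1/y", 0.0, 12.0),
    "disengage_rate": _p(0.30, "1/y", 0.0, 5.0, True),
    "wait_ref_weeks": _p(2.0, "weeks", 0.1, 26.0),
    "reengage_rate": _p(0.12, "1/y", 0.0, 5.0),
    "ed_rate": _p(0.25, "1/y", 0.0, 5.0, True),
    "ed_admit_fraction": _p(0.22, "fraction", 0.0, 1.0),
    "discharge_rate": _p(17.0, "1/y", 0.0, 60.0),
    "post_discharge_exit": _p(1.5, "1/y", 0.0, 12.0),
    "post_attempt_exit": _p(0.35, "1/y", 0.0, 12.0),
    "capacity0_gp": _p(800.0, "appointments/week", 0.0, 1e4),
    "capacity0_specialist": _p(220.0, "appointments/week", 0.0, 1e4),
    "capacity0_community": _p(290.0, "appointments/week", 0.0, 1e4),
    "capacity0_online": _p(150.0, "appointments/week", 0.0, 1e4),
    "capacity0_inpatient": _p(55.0, "admissions/week", 0.0, 1e3),
    "capacity_growth_gp": _p(0.015, "1/y", -0.1, 0.3),
    "capacity_growth_specialist": _p(0.010, "1/y", -0.1, 0.3),
    "capacity_growth_community": _p(0.020, "1/y", -0.1, 0.3),
    "capacity_growth_online": _p(0.050, "1/y", -0.1, 0.3),
    "capacity_growth_inpatient": _p(0.005, "1/y", -0.1, 0.3),
    "gp_consult_freq": _p(6.0, "consultations/y", 0.0, 52.0),
    "specialist_consult_freq": _p(10.0, "consultations/y", 0.0, 52.0),
    # suicidal behaviour
    "attempt_hazard_mod": _p(0.006, "1/y", 0.0, 0.5, True),
    "attempt_hazard_high": _p(0.035, "1/y", 0.0, 0.5, True),
    "attempt_band_mult_youth": _p(1.00, "multiplier", 0.01, 5.0, True),
    "attempt_band_mult_adult": _p(0.60, "multiplier", 0.01, 5.0, True),
    "attempt_band_mult_older": _p(0.35, "multiplier", 0.01, 5.0, True),
    "case_fatality_youth": _p(0.072, "fraction", 0.0, 1.0, True),
    "case_fatality_adult": _p(0.072, "fraction", 0.0, 1.0, True),
    "case_fatality_older": _p(0.072, "fraction", 0.0, 1.0, True),
    # intervention direct effects (scenarios a-f); applied as
    # (1 - effect x uptake) or (1 + effect x uptake) multipliers from 2021
    "effect_aftercare": _p(0.65, "fraction", 0.0, 1.0),
    "uptake_aftercare": _p(0.80, "fraction", 0.0, 1.0),
    "effect_connectedness": _p(0.10, "fraction", 0.0, 1.0),
    "uptake_connectedness": _p(1.00, "fraction", 0.0, 1.0),
    "effect_community_acute": _p(0.06, "fraction", 0.0, 1.0),
    "uptake_community_acute": _p(0.50, "fraction", 0.0, 1.0),
    "effect_crisis_response": _p(0.08, "fraction", 0.0, 1.0),
    "uptake_crisis_response": _p(0.50, "fraction", 0.0, 1.0),
    "effect_coordinated_care": _p(0.30, "fraction", 0.0, 1.0),
    "uptake_coordinated_care": _p(0.50, "fraction", 0.0, 1.0),
    "effect_peer_support": _p(0.30, "fraction", 0.0, 1.0),
    "uptake_peer_support": _p(0.60, "fraction", 0.0, 1.0),
}

# per-care-state multipliers on distress recovery and attempt hazard
_RECOVERY_MULT = (0.80, 0.80, 1.20, 1.50, 1.30, 1.10, 1.50, 1.20, 1.00, 0.70)
_HAZARD_MULT = (1.00, 1.15, 0.75, 0.65, 0.70, 0.90, 0.40, 1.60, 3.50, 1.30)
for _s, _rm, _hm in zip(CARE_STATES, _RECOVERY_MULT, _HAZARD_MULT):
    _PARAM_DEFS[f"recovery_mult_{_s}"] = _p(_rm, "multiplier", 0.01, 10.0)
    _PARAM_DEFS[f"hazard_mult_{_s}"] = _p(_hm, "multiplier", 0.01, 10.0)


class ParameterSet:
    """Named scalar parameters with values, units, bounds, and provenance.

    Behaves like a read-mostly mapping of name -> :class:`Param`.  Use
    :meth:`set_value` / :meth:`with_values` to change values (bounds are
    enforced), and :meth:`compiled` to obtain the flat numeric structure the
    derivative evaluation consumes.
    """

    def __init__(self, params: Mapping[str, Param] | None = None):
        if params is None:
            params = {
                name: Param(v, u, lo, hi, cal)
                for name, (v, u, lo, hi, cal) in _PARAM_DEFS.items()
            }
        self._params: dict[str, Param] = dict(params)

    # -- mapping-ish interface --------------------------------------------
    def __getitem__(self, name: str) -> Param:
        try:
            return self._params[name]
        except KeyError:
            raise ConfigurationError(f"unknown parameter: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params)

    def __len__(self):
        return len(self._params)

    def names(self) -> list[str]:
        return list(self._params)

    def value(self, name: str) -> float:
        return self[name].value

    def values(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.value(n) for n in names])

    def calibratable(self) -> list[str]:
        return [n for n, p in self._params.items() if p.calibrate]

    def set_value(self, name: str, value: float, *, source: str | None = None,
                  clip: bool = False) -> None:
        p = self[name]
        if clip:
            value = min(max(value, p.lower), p.upper)
        if not (p.lower <= value <= p.upper):
            raise ConfigurationError(
                f"{name}={value} outside bounds [{p.lower}, {p.upper}]")
        p.value = float(value)
        if source is not None:
            p.source = source

    def copy(self) -> "ParameterSet":
        return ParameterSet({
            n: Param(p.value, p.unit, p.lower, p.upper, p.calibrate, p.source)
            for n, p in self._params.items()
        })

    def with_values(self, updates: Mapping[str, float], *,
                    source: str | None = None, clip: bool = False
                    ) -> "ParameterSet":
        out = self.copy()
        for n, v in updates.items():
            out.set_value(n, v, source=source, clip=clip)
        return out

    # -- I/O ---------------------------------------------------------------
    def to_yaml(self, path=None) -> str | None:
        doc = {
            n: {"value": p.value, "unit": p.unit, "lower": p.lower,
                "upper": p.upper, "calibrate": p.calibrate, "source": p.source}
            for n, p in self._params.items()
        }
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, path_or_text) -> "ParameterSet":
        if isinstance(path_or_text, str) and "\n" not in path_or_text:
            with open(path_or_text) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(path_or_text)
        base = cls()
        for n, spec in doc.items():
            if n not in base:
                raise ConfigurationError(f"unknown parameter in config: {n!r}")
            p = base[n]
            base._params[n] = Param(
                float(spec["value"]), spec.get("unit", p.unit),
                float(spec.get("lower", p.lower)),
                float(spec.get("upper", p.upper)),
                bool(spec.get("calibrate", p.calibrate)),
                spec.get("source", p.source))
        return base

    def to_csv(self, path=None) -> str | None:
        """Machine-readable parameter dictionary (name, value, unit, bounds,
        calibration flag, source tag)."""
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["name", "value", "unit", "lower", "upper",
                    "calibrate", "source"])
        for n in sorted(self._params):
            p = self._params[n]
            w.writerow([n, p.value, p.unit, p.lower, p.upper,
                        p.calibrate, p.source])
        if path is None:
            return buf.getvalue()
        with open(path, "w", newline="") as fh:
            fh.write(buf.getvalue())
        return None

    # -- compiled numeric view --------------------------------------------
    def compiled(self) -> SimpleNamespace:
        """Flat numeric structure (floats and small arrays) consumed by the
        flow evaluation; rebuild after changing any value."""
        v = self.value
        risk_map = np.array([
            [1 - v("riskmap_low_mod") - v("riskmap_low_high"),
             v("riskmap_low_mod"), v("riskmap_low_high")],
            [1 - v("riskmap_mod_mod") - v("riskmap_mod_high"),
             v("riskmap_mod_mod"), v("riskmap_mod_high")],
            [1 - v("riskmap_high_mod") - v("riskmap_high_high"),
             v("riskmap_high_mod"), v("riskmap_high_high")],
        ])
        if np.any(risk_map < -1e-12):
            raise ConfigurationError("risk->distress mapping rows exceed 1")
        p = SimpleNamespace(
            init_population=v("init_population"),
            birth_rate=v("birth_rate"),
            age_out=np.array([v(f"ageing_rate_{b}") for b in BANDS]),
            migration=np.array([v(f"migration_rate_{b}") for b in BANDS]),
            mortality=np.array([v(f"mortality_{b}") for b in BANDS]),
            cr_up=np.array([v("child_risk_onset"), v("child_risk_escalation")]),
            cr_down=np.array([v("child_risk_recovery_mod"),
                              v("child_risk_recovery_high")]),
            risk_map=risk_map,
            lam1=np.array([v(f"distress_onset_{b}") for b in ADULT_BANDS]),
            lam2=np.array([v(f"distress_escalation_{b}") for b in ADULT_BANDS]),
            rho1=np.array([v(f"distress_recovery_mod_{b}") for b in ADULT_BANDS]),
            rho2=np.array([v(f"distress_recovery_high_{b}") for b in ADULT_BANDS]),
            participation=np.array([v("participation_youth"),
                                    v("participation_adult")]),
            job_loss=np.array([v(f"job_loss_rate_{b}") for b in WORKING_BANDS]),
            job_find=np.array([v(f"job_finding_rate_{b}") for b in WORKING_BANDS]),
            hml_entry=np.array([v(f"homeless_entry_{b}") for b in ADULT_BANDS]),
            hml_exit=np.array([v(f"homeless_exit_{b}") for b in ADULT_BANDS]),
            sub_onset=np.array([v(f"substance_onset_{b}") for b in ADULT_BANDS]),
            sub_remission=v("substance_remission"),
            dv_base=v("dv_base_rate"),
            b_u_d=v("beta_unemployment_distress"),
            b_u_dv=v("beta_unemployment_dv"),
            b_u_h=v("beta_unemployment_homeless"),
            b_dv_d=v("beta_dv_distress"),
            b_h_d=v("beta_homeless_distress"),
            b_d_s=v("beta_distress_substance"),
            b_s_dv=v("beta_substance_dv"),
            b_s_a=v("beta_substance_attempt"),
            b_d_cr=v("beta_distress_childrisk"),
            b_s_cr=v("beta_substance_childrisk"),
            b_dv_cr=v("beta_dv_childrisk"),
            ref_u_band=np.array([v("ref_unemployment_youth"),
                                 v("ref_unemployment_adult")]),
            ref_u_total=v("ref_unemployment_total"),
            ref_dv=v("ref_dv_rate"),
            ref_hml=v("ref_homeless_per10k"),
            ref_high=v("ref_high_distress_prev"),
            ref_sub=v("ref_substance_prev"),
            seek=v("care_seeking_rate"),
            intake=v("intake_rate"),
            triage=np.array([v(f"triage_{s}") for s in AMBULATORY]),
            completion=np.array([v(f"completion_{s}") for s in AMBULATORY]),
            disengage=v("disengage_rate"),
            wait_ref=v("wait_ref_weeks"),
            reengage=v("reengage_rate"),
            ed_rate=v("ed_rate"),
            ed_admit=v("ed_admit_fraction"),
            discharge=v("discharge_rate"),
            pd_exit=v("post_discharge_exit"),
            pa_exit=v("post_attempt_exit"),
            cap0=np.array([v(f"capacity0_{s}") for s in SERVICES]),
            cap_growth=np.array([v(f"capacity_growth_{s}") for s in SERVICES]),
            rec_mult=np.array([v(f"recovery_mult_{s}") for s in CARE_STATES]),
            haz_mult=np.array([v(f"hazard_mult_{s}") for s in CARE_STATES]),
            h_mod=v("attempt_hazard_mod"),
            h_high=v("attempt_hazard_high"),
            band_mult=np.array([v(f"attempt_band_mult_{b}") for b in ADULT_BANDS]),
            case_fatality=np.array([v(f"case_fatality_{b}") for b in ADULT_BANDS]),
        )
        tr = p.triage.sum()
        if tr <= 0:
            raise ConfigurationError("triage shares sum to zero")
        p.triage = p.triage / tr  # normalise
        return p


# --------------------------------------------------------------------------
# Couplings (rate modifiers)
# --------------------------------------------------------------------------


@dataclass
class ModifierSet:
    """Multiplicative rate modifiers implied by the current driver levels.

    Each multiplier follows the linear-elasticity form
    ``max(eps, 1 + beta * (driver / reference - 1))`` and equals 1 when the
    driver sits at its reference level.
    """

    distress_incidence: np.ndarray  # per band (youth, adult, older)
    dv_incidence: float
    homeless_entry: float
    substance_onset: float
    child_risk_escalation: float
    attempt_hazard: float
    dv_rate: float = 0.0  # resulting DV incidence per 100,000/y (auxiliary)

    def as_dict(self) -> dict[str, float]:
        d = {f"distress_incidence_{b}": float(m)
             for b, m in zip(ADULT_BANDS, self.distress_incidence)}
        d.update(dv_incidence=self.dv_incidence,
                 homeless_entry=self.homeless_entry,
                 substance_onset=self.substance_onset,
                 child_risk_escalation=self.child_risk_escalation,
                 attempt_hazard=self.attempt_hazard)
        return d


def _mlin(beta: float, driver: float, ref: float) -> float:
    return max(EPS_MODIFIER, 1.0 + beta * (driver / ref - 1.0))


def _modifiers(y: np.ndarray, p: SimpleNamespace) -> ModifierSet:
    st = ModelState(y)
    pop = st.population
    total = pop.sum()
    pop_15plus = pop[1:].sum()
    if not np.all(np.isfinite(y)):
        raise InvalidStateError("non-finite state values")
    # drivers
    lf = st.employed + st.unemployed
    u_band = np.where(lf > _TINY, st.unemployed / np.maximum(lf, _TINY), 0.0)
    lf_tot = lf.sum()
    u_total = st.unemployed.sum() / lf_tot if lf_tot > _TINY else 0.0
    denom = max(pop_15plus, _TINY)
    high_prev = st.distress[:, 2].sum() / denom
    sub_prev = st.substance_misuse.sum() / denom
    hml_per10k = st.homeless.sum() / max(total, _TINY) * 1e4
    # DV responds to unemployment and substance misuse
    m_dv = (_mlin(p.b_u_dv, u_total, p.ref_u_total)
            * _mlin(p.b_s_dv, sub_prev, p.ref_sub))
    dv_rate = p.dv_base * m_dv
    # distress incidence: band unemployment (youth/adult), DV, homelessness
    common = (_mlin(p.b_dv_d, dv_rate, p.ref_dv)
              * _mlin(p.b_h_d, hml_per10k, p.ref_hml))
    m_dist = np.array([
        _mlin(p.b_u_d, u_band[0], p.ref_u_band[0]) * common,
        _mlin(p.b_u_d, u_band[1], p.ref_u_band[1]) * common,
        common,  # 65+ band has no employment flows
    ])
    m_hml = _mlin(p.b_u_h, u_total, p.ref_u_total)
    m_sub = _mlin(p.b_d_s, high_prev, p.ref_high)
    m_cr = (_mlin(p.b_d_cr, high_prev, p.ref_high)
            * _mlin(p.b_s_cr, sub_prev, p.ref_sub)
            * _mlin(p.b_dv_cr, dv_rate, p.ref_dv))
    m_att = _mlin(p.b_s_a, sub_prev, p.ref_sub)
    return ModifierSet(m_dist, m_dv, m_hml, m_sub, m_cr, m_att, dv_rate)


def compute_rate_modifiers(state: ModelState, params: ParameterSet) -> ModifierSet:
    """Evaluate the inter-component coupling multipliers at a state.

    Implements unemployment -> distress incidence / DV / homelessness entry,
    DV -> distress incidence, homelessness -> distress incidence, high
    distress -> substance-misuse onset, (high distress, substance misuse, DV)
    -> child-risk escalation, and substance misuse -> (DV, attempt hazard).
    """
    state.validate()
    return _modifiers(state.y, params.compiled())


# --------------------------------------------------------------------------
# Service capacity
# --------------------------------------------------------------------------


def service_capacity_at(t: float, params: ParameterSet | SimpleNamespace,
                        population: float) -> np.ndarray:
    """Appointments/week per service at ``t`` years after the start.

    ``capacity(s, t) = capacity0(s) * (population / population0) * (1+g_s)^t``
    — the baseline maintains the configured *per-capita* growth ``g_s``.
    """
    if t < 0:
        raise ConfigurationError("t before simulation start")
    p = params.compiled() if isinstance(params, ParameterSet) else params
    return p.cap0 * (population / p.init_population) * (1.0 + p.cap_growth) ** t


# --------------------------------------------------------------------------
# Flow evaluation
# --------------------------------------------------------------------------


def _deriv(y: np.ndarray, t: float, p: SimpleNamespace) -> np.ndarray:
    """d(state)/dt in persons/year; pure function of (y, t, params)."""
    dy = np.zeros(N_STATE)
    cr = y[I_CR:I_CR + 3]
    D = y[I_D:I_D + 9].reshape(3, 3)
    C = y[I_C:I_C + 30].reshape(3, N_CARE)
    emp = y[I_EMP:I_EMP + 2]
    unemp = y[I_UNEMP:I_UNEMP + 2]
    hml = y[I_HML:I_HML + 3]
    sub = y[I_SUB:I_SUB + 3]

    dcr = dy[I_CR:I_CR + 3]
    dD = dy[I_D:I_D + 9].reshape(3, 3)
    dC = dy[I_C:I_C + 30].reshape(3, N_CARE)
    demp = dy[I_EMP:I_EMP + 2]
    dunemp = dy[I_UNEMP:I_UNEMP + 2]
    dhml = dy[I_HML:I_HML + 3]
    dsub = dy[I_SUB:I_SUB + 3]

    pop = np.empty(4)
    pop[0] = cr.sum()
    pop[1:] = D.sum(axis=1)
    total_pop = pop.sum()

    mods = _modifiers(y, p)

    # ---- demography: births, per-capita drift, ageing-in ----------------
    births = p.birth_rate * total_pop
    dcr[0] += births
    drift = p.migration - p.mortality - p.age_out  # per-capita, per band
    dcr += drift[0] * cr
    dD += drift[1:, None] * D
    dC += drift[1:, None] * C
    demp += drift[1:3] * emp
    dunemp += drift[1:3] * unemp
    dhml += drift[1:, None][:, 0] * hml
    dsub += drift[1:, None][:, 0] * sub

    aging_c = cr * p.age_out[0]             # per risk level
    dD[0] += aging_c @ p.risk_map           # child -> youth, risk -> distress
    dC[0, NIC] += aging_c @ p.risk_map[:, 1:].sum(axis=1)
    aging_c_tot = aging_c.sum()
    lf_y = emp[0] + unemp[0]
    emp_share_y = emp[0] / lf_y if lf_y > _TINY else 0.7
    lf_entry = aging_c_tot * p.participation[0]
    demp[0] += lf_entry * emp_share_y
    dunemp[0] += lf_entry * (1.0 - emp_share_y)

    a_yo = p.age_out[1]                      # youth -> adult
    dD[1] += D[0] * a_yo
    dC[1] += C[0] * a_yo
    demp[1] += emp[0] * a_yo
    dunemp[1] += unemp[0] * a_yo
    dhml[1] += hml[0] * a_yo
    dsub[1] += sub[0] * a_yo

    a_ao = p.age_out[2]                      # adult -> older (leave workforce)
    dD[2] += D[1] * a_ao
    dC[2] += C[1] * a_ao
    dhml[2] += hml[1] * a_ao
    dsub[2] += sub[1] * a_ao
    # older ageing-out (age_out[3], applied in drift) is death bookkeeping

    # conservation accumulators
    dy[I_CUM_BIRTH] = births
    dy[I_CUM_MIG] = float(p.migration @ pop)
    dy[I_CUM_DEATH] = float(p.mortality @ pop) + p.age_out[3] * pop[3]

    # ---- child risk transitions ------------------------------------------
    up1 = p.cr_up[0] * mods.child_risk_escalation * cr[0]
    up2 = p.cr_up[1] * mods.child_risk_escalation * cr[1]
    down1 = p.cr_down[0] * cr[1]
    down2 = p.cr_down[1] * cr[2]
    dcr[0] += -up1 + down1
    dcr[1] += up1 - up2 - down1 + down2
    dcr[2] += up2 - down2

    # ---- distress transitions & coupled care bookkeeping -----------------
    care_pool = C.sum(axis=1)
    cw = C @ p.rec_mult                         # recovery-weighted pool
    r_avg = np.where(care_pool > _TINY, cw / np.maximum(care_pool, _TINY), 1.0)
    f_on = p.lam1 * mods.distress_incidence * D[:, 0]
    f_esc = p.lam2 * mods.distress_incidence * D[:, 1]
    f_r1 = p.rho1 * r_avg * D[:, 1]
    f_r2 = p.rho2 * r_avg * D[:, 2]
    dD[:, 0] += -f_on + f_r1
    dD[:, 1] += f_on - f_esc - f_r1 + f_r2
    dD[:, 2] += f_esc - f_r2
    dC[:, NIC] += f_on                          # newly distressed start out of care
    # recovery to low exits the care partition, weighted by recovery multipliers
    with np.errstate(invalid="ignore", divide="ignore"):
        exit_w = np.where(cw[:, None] > _TINY,
                          C * p.rec_mult[None, :] / np.maximum(cw[:, None], _TINY),
                          0.0)
    dC -= f_r1[:, None] * exit_w

    # ---- care pathway -----------------------------------------------------
    f_seek = p.seek * C[:, NIC]
    dC[:, NIC] -= f_seek
    dC[:, WAIT] += f_seek
    wait_tot = C[:, WAIT].sum()
    cap = p.cap0 * (total_pop / p.init_population) * (1.0 + p.cap_growth) ** t
    cap_yr = cap * WEEKS_PER_YEAR               # service starts per year
    demand = p.intake * p.triage * wait_tot
    served = np.minimum(demand, cap_yr[:4])
    if wait_tot > _TINY:
        band_share = C[:, WAIT] / wait_tot
        served_tot = served.sum()
        dC[:, WAIT] -= served_tot * band_share
        for k, cs in enumerate(_SVC_CARE_STATE):
            dC[:, cs] += served[k] * band_share
        wait_weeks = float(
            (p.triage * (p.triage * wait_tot / np.maximum(cap[:4], _TINY))).sum())
    else:
        wait_weeks = 0.0
    f_dis = p.disengage * (wait_weeks / p.wait_ref) * C[:, WAIT]
    dC[:, WAIT] -= f_dis
    dC[:, DIS] += f_dis
    f_re = p.reengage * C[:, DIS]
    dC[:, DIS] -= f_re
    dC[:, NIC] += f_re
    for k, cs in enumerate(_SVC_CARE_STATE):
        f_done = p.completion[k] * C[:, cs]
        dC[:, cs] -= f_done
        dC[:, NIC] += f_done
    # ED presentations from high distress; a fraction admitted to inpatient
    f_ed = p.ed_rate * D[:, 2]
    adm = p.ed_admit * f_ed
    adm_cap = cap_yr[4]
    adm_tot = adm.sum()
    if adm_tot > adm_cap:
        adm *= adm_cap / adm_tot
    src = C[:, (NIC, WAIT, DIS)]
    src_tot = src.sum(axis=1)
    w = np.where(src_tot[:, None] > _TINY,
                 src / np.maximum(src_tot[:, None], _TINY), 0.0)
    dC[:, NIC] -= adm * w[:, 0]
    dC[:, WAIT] -= adm * w[:, 1]
    dC[:, DIS] -= adm * w[:, 2]
    dC[:, INPT] += adm
    f_disch = p.discharge * C[:, INPT]
    dC[:, INPT] -= f_disch
    dC[:, PDIS] += f_disch
    f_pd = p.pd_exit * C[:, PDIS]
    dC[:, PDIS] -= f_pd
    dC[:, NIC] += f_pd
    f_pa = p.pa_exit * C[:, PATT]
    dC[:, PATT] -= f_pa
    dC[:, NIC] += f_pa

    # ---- suicidal behaviour ----------------------------------------------
    hw = p.h_mod * D[:, 1] + p.h_high * D[:, 2]     # hazard-weighted persons
    h_avg = np.where(care_pool > _TINY, hw / np.maximum(care_pool, _TINY), 0.0)
    att_bs = C * (h_avg * p.band_mult * mods.attempt_hazard)[:, None] \
        * p.haz_mult[None, :]
    att_b = att_bs.sum(axis=1)
    deaths_b = p.case_fatality * att_b
    nonfatal_b = att_b - deaths_b
    dy[I_CUM_SD + 1:I_CUM_SD + 4] += deaths_b
    dy[I_CUM_SH + 1:I_CUM_SH + 4] += nonfatal_b
    dy[I_CUM_ED] = f_ed.sum() + att_b.sum()          # attempts present to ED
    dy[I_CUM_PSY] = adm.sum()
    # removals: all attempters leave their care state; survivors re-enter at
    # post_attempt, deaths leave the distressed pool by hazard-weighted level
    dC -= att_bs
    dC[:, PATT] += nonfatal_b
    share_mod = np.where(hw > _TINY, p.h_mod * D[:, 1] / np.maximum(hw, _TINY), 0.0)
    dD[:, 1] -= deaths_b * share_mod
    dD[:, 2] -= deaths_b * (1.0 - share_mod)
    # suicide mortality drains auxiliary partitions pro rata
    sd_rate = np.where(pop[1:] > _TINY, deaths_b / np.maximum(pop[1:], _TINY), 0.0)
    demp -= sd_rate[:2] * emp
    dunemp -= sd_rate[:2] * unemp
    dhml -= sd_rate * hml
    dsub -= sd_rate * sub

    # ---- determinants -----------------------------------------------------
    f_loss = p.job_loss * emp
    f_find = p.job_find * unemp
    demp += f_find - f_loss
    dunemp += f_loss - f_find
    housed = np.maximum(pop[1:] - hml, 0.0)
    f_henter = p.hml_entry * mods.homeless_entry * housed
    f_hexit = p.hml_exit * hml
    dhml += f_henter - f_hexit
    clean = np.maximum(pop[1:] - sub, 0.0)
    f_sonset = p.sub_onset * mods.substance_onset * clean
    f_srem = p.sub_remission * sub
    dsub += f_sonset - f_srem

    return dy


def derivatives(state: ModelState, params: ParameterSet, t: float = 0.0
                ) -> np.ndarray:
    """Evaluate every stock's time derivative (persons/year).

    Returns a vector in the :class:`ModelState` layout; wrap it with
    ``ModelState(derivatives(...))`` for named access.  Raises
    :class:`InvalidStateError` on negative or non-finite input stocks; the
    simulation engine (not this function) guards against flow-induced
    negativity within a step.
    """
    state.validate()
    return _deriv(state.y, t, params.compiled())


def dv_incidence_rate(state: ModelState, params: ParameterSet) -> float:
    """Current domestic-violence incidence (per 100,000/y), an auxiliary
    rate driven by unemployment and substance misuse."""
    return _modifiers(state.y, params.compiled()).dv_rate
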