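"""The intervention scenario library (a–u) as declarative parameter modifiers.

Each scenario is a named set of multiplicative modifications to model
parameters, switched on as a step at its start date (1 January 2021 by
default, no ramp).  Social-determinant scenarios (i–r) map directly to the
quoted rate multipliers; mental-health service scenarios (a–f) translate an
intervention's direct effect size and uptake fraction into multipliers on
the mechanism parameters they act through.  Combination scenarios compose
multiplicatively on any overlapping parameter.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

from .model_core import ConfigurationError, ParameterSet

DEFAULT_START = _dt.date(2021, 1, 1)

SCENARIO_IDS = tuple("abcdefghijklmnopqrstu")

_NAMES = {
    "a": "Post-attempt assertive aftercare",
    "b": "Social connectedness programs",
    "c": "Community-based acute care services",
    "d": "Technology-enabled crisis response",
    "e": "Technology-enabled coordinated care",
    "f": "Post-discharge peer support",
    "g": "Aftercare + connectedness + coordinated care",
    "h": "All mental health and suicide prevention interventions",
    "i": "Reducing childhood adversity by 20%",
    "j": "Reducing childhood adversity by 50%",
    "k": "Increasing youth employment by 20%",
    "l": "Increasing youth employment by 50%",
    "m": "Reducing (total) unemployment by 20%",
    "n": "Reducing (total) unemployment by 50%",
    "o": "Reducing domestic violence by 20%",
    "p": "Reducing domestic violence by 50%",
    "q": "Reducing homelessness by 20%",
    "r": "Reducing homelessness by 50%",
    "s": "Childhood adversity -50% + youth employment +50%",
    "t": "All social determinants in combination",
    "u": "Best services combination + best determinants combination",
}


@dataclass
class Scenario:
    """A named, time-triggered set of multiplicative parameter modifications."""

    id: str
    name: str
    start: _dt.date = DEFAULT_START
    modifications: dict[str, float] = field(default_factory=dict)
    uptake: float | None = None

    def __post_init__(self):
        for k, m in self.modifications.items():
            if m <= 0:
                raise ConfigurationError(f"non-positive multiplier for {k!r}")

    @classmethod
    def baseline(cls) -> "Scenario":
        return cls("baseline", "Business as usual")

    def apply(self, params: ParameterSet, t: float) -> ParameterSet:
        """Effective parameters at ``t`` years since 2011; pure function.

        Before the scenario start the input is returned unmodified; at or
        after it, each named parameter is multiplied by its modifier
        (clipped into the parameter's bounds).
        """
        start_t = (self.start.year - 2011) + (
            self.start - _dt.date(self.start.year, 1, 1)).days / 365.25
        if t < start_t or not self.modifications:
            return params
        out = params.copy()
        for name, mult in self.modifications.items():
            if name not in params:
                raise ConfigurationError(
                    f"scenario {self.id!r} modifies unknown parameter {name!r}")
            out.set_value(name, params.value(name) * mult, clip=True)
        return out

    def compose(self, other: "Scenario", id: str | None = None,
                name: str | None = None) -> "Scenario":
        """Combine two scenarios; overlapping modifications multiply."""
        mods = dict(self.modifications)
        for k, m in other.modifications.items():
            mods[k] = mods.get(k, 1.0) * m
        return Scenario(id or f"{self.id}+{other.id}",
                        name or f"{self.name} + {other.name}",
                        min(self.start, other.start), mods)


def _scale(params: ParameterSet, effect: str, uptake: str) -> float:
    # hazard/rate multiplier implied by a direct effect size and its uptake
    return 1.0 - params.value(effect) * params.value(uptake)


def build_scenario(id: str, params: ParameterSet | None = None,
                   start: _dt.date = DEFAULT_START) -> Scenario:
    """Construct one of the library scenarios (a–u) or ``"baseline"``.

    Service-intervention multipliers (a–f) are derived from the effect-size
    and uptake parameters in ``params`` (reference defaults if omitted).
    """
    if id == "baseline":
        return Scenario.baseline()
    if id not in SCENARIO_IDS:
        raise KeyError(f"unknown scenario id {id!r}")
    if params is None:
        params = ParameterSet()
    bld = lambda sid: build_scenario(sid, params, start)

    if id == "a":
        # aftercare lowers the elevated post-attempt hazard
        m = _scale(params, "effect_aftercare", "uptake_aftercare")
        mods = {"hazard_mult_post_attempt": m}
        up = params.value("uptake_aftercare")
    elif id == "b":
        # universal connectedness programs lower distress incidence flows
        m = _scale(params, "effect_connectedness", "uptake_connectedness")
        mods = {f"distress_{k}_{b}": m
                for k in ("onset", "escalation")
                for b in ("youth", "adult", "older")}
        up = params.value("uptake_connectedness")
    elif id == "c":
        # community acute care resolves crises that would otherwise escalate
        # among people out of care or waiting (ED diversion channel)
        m = _scale(params, "effect_community_acute", "uptake_community_acute")
        mods = {"hazard_mult_not_in_care": m, "hazard_mult_waiting": m}
        up = params.value("uptake_community_acute")
    elif id == "d":
        # technology-enabled crisis response reaches waiting and disengaged
        m = _scale(params, "effect_crisis_response", "uptake_crisis_response")
        mods = {"hazard_mult_waiting": m, "hazard_mult_disengaged": m}
        up = params.value("uptake_crisis_response")
    elif id == "e":
        # coordinated multidisciplinary care: faster in-care recovery,
        # less disengagement
        e = params.value("effect_coordinated_care") \
            * params.value("uptake_coordinated_care")
        mods = {f"recovery_mult_{s}_care": 1.0 + e
                for s in ("gp", "specialist", "community", "online")}
        mods["disengage_rate"] = 1.0 - e
        up = params.value("uptake_coordinated_care")
    elif id == "f":
        # peer support after discharge: lower post-discharge hazard, faster
        # stable transition out of the post-discharge state
        e = params.value("effect_peer_support") * params.value("uptake_peer_support")
        mods = {"hazard_mult_post_discharge": 1.0 - e,
                "post_discharge_exit": 1.0 + e}
        up = params.value("uptake_peer_support")
    elif id == "g":
        sc = bld("a").compose(bld("b")).compose(bld("e"))
        return Scenario("g", _NAMES["g"], start, sc.modifications)
    elif id == "h":
        sc = bld("a")
        for o in "bcdef":
            sc = sc.compose(bld(o))
        return Scenario("h", _NAMES["h"], start, sc.modifications)
    elif id in "ij":
        m = 0.8 if id == "i" else 0.5
        mods = {"child_risk_onset": m, "child_risk_escalation": m}
        up = None
    elif id in "kl":
        m = 1.2 if id == "k" else 1.5
        mods = {"job_finding_rate_youth": m}
        up = None
    elif id in "mn":
        m = 0.8 if id == "m" else 0.5
        mods = {"job_loss_rate_youth": m, "job_loss_rate_adult": m}
        up = None
    elif id in "op":
        m = 0.8 if id == "o" else 0.5
        mods = {"dv_base_rate": m}
        up = None
    elif id in "qr":
        m = 0.8 if id == "q" else 0.5
        mods = {"homeless_entry_youth": m, "homeless_entry_adult": m,
                "homeless_entry_older": m}
        up = None
    elif id == "s":
        sc = bld("j").compose(bld("l"))
        return Scenario("s", _NAMES["s"], start, sc.modifications)
    elif id == "t":
        sc = bld("j")
        for o in "lnpr":
            sc = sc.compose(bld(o))
        return Scenario("t", _NAMES["t"], start, sc.modifications)
    elif id == "u":
        sc = bld("g").compose(bld("s"))
        return Scenario("u", _NAMES["u"], start, sc.modifications)
    else:  # pragma: no cover
        raise KeyError(id)
    return Scenario(id, _NAMES[id], start, mods, up)


def scenario_library(params: ParameterSet | None = None) -> dict[str, Scenario]:
    """All 21 scenarios plus baseline, keyed by id."""
    lib = {"baseline": Scenario.baseline()}
    lib.update({sid: build_scenario(sid, params) for sid in SCENARIO_IDS})
    return lib
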