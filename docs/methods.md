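# Methods

## Model structure

The model is a deterministic continuous-time stock-flow system over a
regional population, integrated by explicit Euler at a fixed step of
0.4375 days (one sixteenth of a week) — the standard system-dynamics
convention — from 1 January 2011 for 30 years.  Calendar years are 365.25
days; the forecast window "2021–2041" is the half-open interval
[2021-01-01, 2041-01-01).

### Population

Four age bands: children 0–14, youth 15–24, adults 25–64, older people 65+.
Births (a per-capita rate on the total population) enter the child band;
ageing moves people between consecutive bands at 1/width per year.  The
open-ended 65+ band uses a 20-year expected residence, and its ageing-out
flow is counted as background mortality.  Net migration and background
mortality are per-capita, per-band rates applied proportionally to every
partition stock, so partitions (distress levels, care states, labour-force
status, homelessness, substance misuse) remain consistent with band
populations through all demographic flows.  Band populations are *derived*
(sums of the partitions), never stored separately, which makes the
partition invariants exact by construction.

### Psychological distress

Each band 15+ is partitioned into low (K10 10–15), moderate (K10 16–21) and
high/very-high (K10 22–50) psychological distress.  Onset (low→moderate)
and escalation (moderate→high) rates are band-specific and multiplied by
the social-determinant modifier; recovery rates (moderate→low, high→
moderate) are multiplied by the care-mix average of the per-care-state
recovery multipliers, so people in treatment recover faster than people out
of care.  Children carry *risk of developing a mental disorder* (low /
moderate / high) instead of K10 distress; when children age into the youth
band their risk level maps to an initial distress distribution (high risk
seeds high distress with probability 0.55 under the defaults).  This
mapping is the channel through which childhood-adversity interventions act,
and it is deliberately strong enough — together with slow within-youth
distress dynamics — that entrant composition materially shapes youth
distress, giving childhood-adversity reduction its delayed, amplifying
effect.

### Social determinants and couplings

Unemployment (employed/unemployed stocks for youth and adults), homelessness
and substance misuse (stocks per band 15+), and domestic-violence incidence
(an auxiliary rate in incidents per 100,000/year, not a stock, since it is
reported as an incidence) interact through multiplicative modifiers of the
linear-elasticity form

    multiplier = max(ε, 1 + β · (driver / driver_ref − 1)),  ε = 0.01.

The implemented couplings: unemployment → distress incidence (band-specific
for youth/adults), unemployment → DV, unemployment → homelessness entry,
DV → distress incidence, homelessness → distress incidence, high-distress
prevalence → substance-misuse onset, substance misuse → DV and attempt
hazard, and (high distress, substance misuse, DV) → child-risk escalation
(adverse early-life exposure).  The linear form was chosen because only the
directions of these effects are established; it is sign-correct around the
reference point, calibratable through the β elasticities, and floored at
0.01 to keep rates positive.  Reference driver levels are parameters set to
the 2011 regional values, so all modifiers start at 1.

### Mental health services

Distressed people (moderate + high) occupy exactly one care state:
out of care, waiting, GP care, psychiatrist/allied care, community care,
online care, inpatient, post-discharge, post-attempt, or disengaged.  A
single waiting pool with fixed triage shares feeds the four ambulatory
services rather than per-service queues (this keeps the state count
tractable; per-service waiting time is the queue/capacity ratio).  Service
intake is capped by capacity, which grows as
`capacity₀ · (population/population₀) · (1+g)^t` — the baseline maintains
current per-capita capacity growth.  Disengagement from waiting rises
linearly with the mean waiting time; ED presentations arise from high
distress, a fraction are admitted to inpatient care (capacity-capped) and
discharged into a post-discharge state.  Care states carry multipliers on
both recovery rates and attempt hazards (e.g. inpatient 0.4, post-discharge
1.6, post-attempt 3.5 under the defaults).

### Suicidal behaviour

Attempt events arise from the distressed pool at hazards by distress level,
scaled by band multipliers, the care-state hazard multiplier, and the
substance-misuse modifier.  A case-fatality fraction of attempts are
suicide deaths (removed from the population); the nonfatal remainder are
self-harm hospitalisations and move to the elevated-hazard post-attempt
state, which decays back to out-of-care at 0.35/year (≈3-year elevation).
Deaths and hospitalisations accumulate in per-band accumulator stocks, so
cumulative 2021–2041 outputs are exact differences of accumulators and
independent of the storage stride.  Modelling deaths as the fatal fraction
of attempts subsumes the question of whether deaths require a preceding
attempt event; no separate death process is needed.

## Numerical choices

- **Integrator**: explicit Euler at dt = 0.4375 d.  Step-halving changes
  cumulative 2021–2041 outputs by well under 0.1% (asserted in the tests).
- **Flow limiting**: any stock driven below zero within a step is floored
  at zero and the event counted on the trajectory.  Under the reference
  parameterisation this never fires (asserted); it guards extreme parameter
  draws.  The floor sacrifices exact conservation only on the steps where
  it fires, which is logged.
- **Degenerate inputs**: empty pools (zero waiting, zero distressed) use
  guarded divisions and produce zero flows; non-finite states abort the run
  naming the step.
- **Determinism**: identical inputs produce bitwise-identical trajectories;
  a scenario whose multipliers are all exactly 1 is bitwise the baseline.

## Calibration

Free parameters (any subset flagged calibratable; the shipped default set
is the attempt hazards, case-fatality fractions and the unemployment→
distress elasticity) are fitted by minimising the **sum over observed
series of the mean absolute percent error** between annual observations and
the matching simulated annual indicators, using Powell's derivative-free
direction-set method.  Bounds are enforced by scipy's bounded Powell plus a
clamp-with-quadratic-penalty inside the objective (keeping the objective
finite and derivative-free-friendly); simulation failures return a large
finite penalty.  Optional restarts jitter the initial guess (seeded).  The
returned parameter vector is never worse than the initial guess.  Series
are fitted on rates (per 100,000 or percent), unweighted; calibration runs
use a weekly integration step, which changes annual indicators negligibly
relative to the default step and keeps a full Powell search to tens of
seconds.

## Scenarios

Social-determinant scenarios i–r multiply exactly the stated rates by
exactly the stated factors (×0.8/×0.5; ×1.2/×1.5 for youth job-finding)
from 1 January 2021, as a step with no ramp.  Service interventions a–f
translate a direct effect size and an uptake fraction into multipliers on
their mechanism parameters:

- **a** post-attempt aftercare → post-attempt hazard multiplier ×(1−e·u);
- **b** social connectedness → all distress onset/escalation rates (universal);
- **c** community-based acute care → hazards of people out of care/waiting
  (crisis resolution in the community, the ED-diversion channel);
- **d** technology-enabled crisis response → hazards of waiting/disengaged
  people (a reach channel distinct from c by design);
- **e** technology-enabled coordinated care → in-care recovery multipliers
  up, disengagement down;
- **f** post-discharge peer support → post-discharge hazard down, stable
  transition out of post-discharge up.

Combinations (g, h, s, t, u) compose multiplicatively on overlapping
parameters.  Effect sizes and uptakes ship as reference defaults
(source tag `reference-default`) and are overridable from the parameter
config, like every other parameter.

## Sensitivity analysis

Latin hypercube sampling draws n parameter sets (default 100) from a
uniform joint distribution spanning ±20% of the defaults of the six
intervention direct effects and the five per-service capacity growth
rates, with exactly one sample per marginal equal-width bin.  Each sampled
set replaces the defaults in **both** the baseline and the scenario run
(paired differencing; capacity growth is a baseline property, while
intervention effects are inert in the baseline by construction).  Percent
reductions are summarised by the mean and the empirical 2.5th/97.5th
percentiles (linear-interpolation quantiles).  These 95% intervals measure
the impact of assumed-effect uncertainty and are not confidence intervals.

## Synthetic data

The generator stands in for the regional administrative datasets, which are
confidential.  A ground-truth parameterisation (the reference defaults)
is simulated 2011–2017 and annual indicator series are emitted with
multiplicative lognormal noise of a configurable coefficient of variation
(default 5%; rates are positive and measurement error plausibly
proportional).  The truth run is checked against the published regional
anchors — 2016 population 502,524 (simulated within 0.1%), 2017 suicide
rate 16.6 per 100,000 (simulated within 5%), youth share 10.4% — and
generation fails loudly if any anchor is missed by more than 25%.
LGA-level extremes (unemployment 9.7%, DV 757.1 per 100,000, homelessness
57.5 per 10,000) are treated as upper bounds for the region-wide series.
The pre-2011 rise in the suicide rate is out of scope: the truth is tuned
to land near the 2017 anchor over 2011–2017, not to reproduce 2006 levels.
What passing tests show is therefore that the *pipeline* (simulation,
calibration, scenario and sensitivity machinery) is correct and that
parameters are recoverable from data the model itself could have produced
— not that the reference parameterisation reproduces the real region's
microdata, seasonality, or reporting artefacts, which the generator does
not emulate.

## Reference parameterisation

All defaults were chosen once so the uncalibrated model is consistent with
the regional anchors and the broad shape of the published projections
(business-as-usual cumulative counts within ~10–15%; social connectedness
the strongest single intervention; childhood adversity the strongest
youth-focused determinant with an amplifying effect; combined scenarios
approaching a plateau).  Every default carries bounds, a calibration flag
and a `reference-default` source tag, and is replaceable from a YAML
config without code changes.  Problem sizes used by the shipped tests and
the acceptance script — weekly integration steps for calibration and
sensitivity runs, 40 Latin-hypercube rows, three free parameters in the
recovery harness — were chosen to keep a full run to minutes on one CPU
while leaving the default-step results unchanged to the tolerances quoted
above.

## Known limitations

- No agent-level heterogeneity, geographic sub-catchments, or separate
  modelling of Aboriginal and Torres Strait Islander populations; no
  economic outputs.
- The care pathway uses one waiting pool with triage shares, not
  per-service queues; care states are not cross-classified by distress
  level (within a care state, the moderate/high mix is assumed equal to the
  band aggregate).
- Attempts are deterministic flows, not sampled events, so the model gives
  expected counts without demographic stochasticity.
- Flow limiting floors stocks at zero rather than proportionally rationing
  gross outflows; under the reference parameterisation it never activates.
- The 21 scenarios switch on as steps in 2021; ramp-up is supported by the
  data model but not configured.
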