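# Methods

This note documents the models, their parameters and the design choices
behind them, in the order a simulation flows: survival, excavation,
scenario simulation, rule engines, synthetic data.

## Survival at extrication

A buried subject's survival probability is modelled as

    P(t, d) = clamp( S(t) − r(t) · (d − m(t)) / 100, 0, 1 )

with burial duration `t` in minutes and burial depth `d` in cm.

**Baseline curve `S(t)`.** European accident statistics constrain the
shape, not the level: survival falls by 70 percentage points over the
first 35 minutes of burial, and by almost 3 points per minute between 15
and 35 minutes. The published sources do not print `S(0)`, so the default
anchors it at 0.91 with breakpoints (0, 0.91), (15, 0.81), (35, 0.21),
(130, 0.05), linear in between and constant beyond — this realizes the
70-point drop exactly and a 3.0 points/min slope in the 15–35 min window.
The "70%" drop is read as 70 percentage points (not a relative factor),
because the companion statement "thus a decrease of 2% per minute"
(70/35) is linear in points. All breakpoints are configurable.

**Mean-depth trend `m(t)`.** Subjects excavated later tend to lie deeper;
the published trend is linear but its coefficients are not printed. The
default `m(t) = 80 + 0.5·t` cm reaches ≈95–100 cm around the 30–40 min
mark, consistent with the printed 100 cm overall median depth and 30 min
mean duration, and ~140 cm at two hours.

**Depth correction `r(t)`.** Deeper burials kill more at equal duration,
with the greatest per-metre impact inside the first 40 minutes of burial
(shorter supply of air pockets at depth); the published figure's numeric
values are not printed. The default uses four half-open duration bins:

| duration bin (min) | survival cost per metre |
|---|---|
| [0, 20) | 0.25 |
| [20, 40) | 0.13 |
| [40, 60) | 0.05 |
| [60, ∞) | 0.03 |

Because these values are unprinted, they were calibrated — once, within
the qualitative constraints (non-increasing, largest inside the first
40 min) — against the three *printed* Monte Carlo outcomes they drive:
the survival-optimal triage threshold of 150 cm in hard debris, the same
threshold in soft debris, and the ≈0.5 additional lives saved by
postponing a 300 cm first burial. A coarser two- or three-bin structure
can reproduce any two of those three outcomes but not all three: the
hardness-independence of the threshold hinges on whether a postponed
marginal subject's extrication time escapes the heavy-penalty bins, which
requires the finer granularity around 20–40 min. The correction is
additive in probability points, symmetric above/below the mean depth
(shallower-than-average burials score above the baseline), clamped to
[0, 1]. Bins are half-open `[lower, upper)`; a duration exactly on an
edge takes the bin it opens.

## Excavation

The snow conveyor belt must keep its ramp angle below 26° (measured field
threshold above which snow slides back), giving

    belt length = depth · tan(90° − 26° − slope)

rounded to the nearest cm. Staffing divides the belt into nominal 80 cm
segments per rescuer, rounding to the nearest count (ties up — the
conservative direction) with a minimum of one, and adds a rescuer whenever
a segment would stretch beyond 90 cm. This rule reproduces both printed
cases (180 cm → 2 rescuers at 90 cm each; 150 cm → 2 rescuers); whether
the source staffing chart uses floor, round or a lookup table is not
determinable from text, so round-to-nearest is a documented choice
validated against those two cases.

Dig time is `depth / rate` with team-level median rates of 13.20 cm/min
(hard debris: hand-hardness one finger or harder) and 25.32 cm/min (soft:
four fingers or softer), valid when the team is at least the required
size. An optional `staffing_factor` in (0, 1] scales the rate down for
sensitivity analyses of understaffed teams; it is plumbing, not a claim
from the source data.

## Two-burial scenario engine

One team, two buried subjects, sequential work. Under the *immediate*
policy, subject 1 is excavated on being found, treated for
`treatment_min` (default 10 min — 4 min of search/extrication plus the
6 min CPR budget), then the team searches for and excavates subject 2.
Under the *postpone* policy (taken when subject 1's depth is at or beyond
the threshold), the team searches for subject 2 first and excavates the
shallower subject first; if subject 2 turns out at least as deep as
subject 1 (margin configurable, default 0 — "excavate the shallower
subject first" exactly), the team returns to subject 1. Survival is read
off `P(t, d)` at each subject's extrication time; the per-case score is
`p1 + p2` ∈ [0, 2] expected lives. Both subjects are assumed not to be in
cardiac arrest until extricated; staffing is assumed adequate, so the
team dig rates apply as-is.

The threshold sweep evaluates candidate thresholds 100–300 cm in 10 cm
steps, 1000 cases per threshold by default, drawing **one** stream of
depth pairs per sweep and reusing it across thresholds (common random
numbers). This makes the mean-lives curve piecewise constant between
sampled depths and the argmax stable at 1000 cases; ties resolve to the
lowest threshold. The mean-lives profile is intrinsically flat within
±30 cm of the optimum (differences of ~0.002 lives), so the reported
optimum carries a one-grid-step uncertainty at this case count. A full
default sweep takes about a second on one CPU; the acceptance script's
complete run (sweep, policy comparison at 20 000 draws, calibration
statistics at 100 000 draws) takes a few seconds.

With the default parameters the engine yields: optimal threshold 150 cm
in both hard and soft debris (±one grid step across seeds), ≈0.90 mean
lives saved at the 150 cm threshold in the 10/10/5 hard-debris scenario,
≈+0.43 lives from postponing a 300 cm first burial, and a soft-vs-hard
mean-lives gap that shrinks monotonically (≈0.14 → 0.10 → 0.07 → 0.02)
as search durations grow across the four scenario presets (5/10/5,
10/10/5, 25/10/5, 40/10/10 minutes).

## Rule engines

**Resource shortage** is fewer than two rescuers per remaining buried
subject (false at exact equality and when nobody is left buried).
**Postponement** requires shortage *and* depth ≥ 150 cm (inclusive).
**Injuries incompatible with life** is the avalanche-specific disjunction:
obvious severe mechanical impact, high fall, severe collision with trees
or rocks, or a head/truncal position incompatible with life.

**BLS sequencing.** Under shortage, conscious patients without
life-threatening injuries are postponed before any treatment; those who
are alert with clear answers, uninjured and at worst hypothermia stage 1
may be enlisted as rescuers (always with monitoring). Everyone else:
clear the airway if needed, check breathing, and if breathing is not
normal — agonal breathing is never a sign of life — give five rescue
breaths before anything else. Patients with vital signs after the breaths
continue under wilderness first aid; those without enter 30:2 CPR.

**CPR budget.** Normothermia is operationalized purely as burial duration
≤ 60 min (hypothermic arrest essentially does not occur earlier; surface
temperature estimates by cold, stressed rescuers are deliberately not an
input). Normothermic arrest under shortage: 6 minutes (three 2-minute
windows) — beyond that, the survival cost to the still-buried exceeds the
resuscitation benefit. Without shortage: unlimited (until handover,
rescuer danger, or incompatible injuries — modelled as disposition flags,
not timers). Burial > 60 min with a fully obstructed airway and no air
pocket: zero (no gas exchange was possible). Burial > 60 min otherwise
(partial exchange possible, or airway unknown): unlimited. The budget
does not reset if vital signs return and are lost again.

**Defibrillation.** Potentially hypothermic patients (burial > 60 min):
at most three shocks; otherwise standard AED guidance (no cap).

**Hypothermia staging** from AVPU only (shivering deliberately excluded):
A → stage 1 (move actively, warm sugary drink); V → stage 2 (insulate,
heat packs, drink only if able to swallow with the upper body inclined);
P → stage 3 (insulate, heat packs); U without vital signs → stage 4
(effective CPR). An unresponsive patient *with* preserved vital signs has
no canonical stage on this branch and is mapped to the stage-3 bundle
with an explicit warning — conservative, avoiding a stage-4 declaration
in a perfusing patient.

**Intermittent CPR.** Assuming arrest at 30 °C immediately before the
head is reached, the implied cooling gradient is 7 °C divided by the
burial duration in hours; cooling the further 2 °C to the 28 °C
iCPR threshold takes `burial/3.5`, applied as `burial/3` for a safety
margin (the exact value is exposed for reporting alongside the applied
one). The timetable is ≥5 min CPR on / ≤5 min off, so the first
interruption comes no earlier than `burial/3 + 5` min — 25 min at the
60-min boundary. Eligibility starts at 60 min (the published boundary
case is computed at exactly 60), while the CPR-budget rule treats
≤ 60 min as normothermic; the 30 °C/28 °C temperatures are embodied in
the /3 rule and never surface as a patient field.

## Synthetic accident records

The generator emulates the *printed* summary statistics of a proprietary
1070-burial European dataset; it does not and cannot reproduce the
record-level structure.

* **Depth**: log-normal, median 100 cm, shape σ = 0.60, truncated to
  [10, 600] cm, sampled by inverse CDF. σ is unprinted upstream; it was
  fixed once at a value that keeps the simulated 150 cm threshold stable
  and is configurable.
* **Duration**: two-component log-normal mixture truncated to
  [1, 96] min: weight 0.764 on a short-burial component
  (log-mean 2.894, log-sd 0.674 — median ≈18 min) and 0.236 on a
  long-burial component concentrated near 62 min. The four printed
  statistics (42/62/71% excavated by 20/40/60 min; mean 30 min) are
  mutually inconsistent for any smooth right-tailed distribution —
  matching the three quantiles exactly forces a mean ≥ 33.3 min — so the
  fit pins the 20-min quantile and the mean (the two statistics with
  published-value tolerances used in the tests) and minimizes the misfit
  of the other two. Residual misfit: the fitted law puts ≈68% by 40 min
  and ≈75% by 60 min (+5.6 / +4.1 points). The truncation at 96 min is
  required by the mean constraint and means the generator produces no
  multi-hour burials.
* **Air pocket**: Bernoulli with logistic probability
  `expit(0.10 − 0.0277·depth)`, calibrated so the conditional median
  depths are ≈59 cm (pocket) and ≈106 cm (no pocket) against the printed
  60 vs 100 cm. The implied pocket prevalence (≈10%) is forced by those
  two medians given a common 100 cm overall median; it is lower than
  field prevalence, which the printed statistics cannot jointly encode.
* **Hardness**: scenario-level in the sweep (as in the simulation design);
  the per-record Bernoulli (default p = 0.5, a neutral placeholder) exists
  only for dataset realism.

Depth and duration are sampled independently even though the mean-depth
trend rises with duration: the survival model already conditions its
depth correction on duration, and the scenario simulation draws depths
unconditionally. Each field uses an independent substream of the master
seed, so all sampling is reproducible and enlarging one field's sample
does not reshuffle the others.

**What passing tests do and do not show.** The generator matches the
printed headline statistics, and the scenario results derived from it
match the printed Monte Carlo outcomes; but real accident data are
lumpier (discrete depth reporting, correlated depth/duration, terrain
covariates), so agreement here demonstrates internal consistency of the
model chain, not validation against field data.

## Numerical choices and degenerate inputs

Durations in minutes, depths/lengths in cm, angles in degrees;
probabilities are fractions internally and percentages only in rendered
tables. Belt length rounds half-up to the nearest cm (matching the
printed 180); staffing ties round up. A slope exactly at 90° − ramp angle
yields a zero-length belt; steeper slopes are a geometry error. Negative
durations/depths, zero-or-negative staffing factors, empty threshold
grids and contradictory patient states (alert without vital signs, normal
plus agonal breathing) raise `ValueError` at construction. Zero-depth
burials dig in zero time; a zero-record dataset round-trips as a
header-only CSV.

## Known limitations

Two buried subjects and one sequential team only; no multi-team
parallelism, no probing strategy, no terrain-zone scoring. Survival is
evaluated at extrication (no model of deterioration during treatment).
The depth-correction bin values and the depth-distribution shape are
calibrated to printed aggregate outcomes, not fitted to record-level
data; conclusions sensitive to the tails of either should be re-derived
from real data. The duration generator's 96-min cap excludes multi-hour
burials, so it must not be used to study long-burial epidemiology.
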