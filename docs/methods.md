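# Methods

## Model structure and assumptions

The cohort process is a discrete-time Markov chain on six states with a
13-week cycle (Δt = 13/52 = 0.25 years exactly; no calendar-day
accounting). Phase 1 holds the two complication-free states, split at a
JAK2 V617F allele burden of 50%; phase 2 the three progression states
(acute leukemia, myelofibrosis, thrombosis); phase 3 is death.

Assumptions, in the order they bind:

- **Burden acts only through progression.** Complication-free patients die
  at general-population rates regardless of burden; the burden changes the
  per-cycle probabilities of myelofibrosis and thrombosis (and, by
  construction, not leukemia). Survival differences between burden groups
  are therefore entirely mediated by progression.
- **Competing events are resolved by a direct multinomial split.** The
  published per-cycle probabilities are used as-is, with stay-probability
  1 − Σ(exits); a configuration whose exits exceed 1 is rejected with an
  error naming the state and cycle. No rate-summation correction is
  applied: the largest base-case exit sum is ≈ 0.03, where the difference
  between conventions is far below every tolerance used here.
- **Progression states are absorbing until death** (no thrombosis → MF
  etc.), with age-independent complication-specific mortality. By default a
  patient entering a progression state is first exposed to its mortality
  the following cycle; `same_cycle_progression_death=True` switches to
  same-cycle exposure (worth ≲ 0.07 LY on 20-year OS in the base case).
  `phase2_background_floor=True` additionally composes background mortality
  into progression states, for sensitivity use; off by default, since the
  phase logic assigns complication-specific mortality only.
- **The cohort, not the patient, has a burden trajectory.** Each cycle the
  surviving complication-free mass is re-split between the two burden
  groups to match a target proportion π(t); mass can move in both
  directions. This models a cohort-level marker distribution rather than
  individual marker paths.

## Cycle-parameter construction

All source risks are mapped to cycle probabilities under a constant
(exponential) hazard: a cumulative incidence P over t years gives
r = −ln(1−P)/t per year; a rate gives p = 1 − exp(−r·Δt) per cycle; an
annual probability q gives 1 − (1−q)^0.25. The conversions are mutually
consistent (identical underlying assumption; the round trip is exact to
machine precision) and reproduce, after scaling to per-100-person-years and
one-decimal rounding, every published annual-rate/cumulative-incidence pair
used in validation. Weibull or other non-constant hazard shapes are out of
scope.

## Parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| `start_age` | 57 | years | reference cohort's starting age |
| `horizon_years` | 20 | years | 80 cycles; standard long-term horizon |
| progression/mortality risks | base-case catalog | per 13-week cycle | the flagged source per transition; alternatives span the scenario space |
| life table | synthetic Gompertz–Makeham | annual qx | see below |
| trajectory | mean burden 42.8% → 37% over 12 cycles, σ = 20 pp | % / pp | see below |
| `half_cycle_correction` | off | — | the AUC convention is a left Riemann sum; trapezoid available behind the flag |

The base-case risk catalog: thrombosis 0.004/0.009 (low/high burden),
leukemia 0.00073 (both groups), myelofibrosis 0.0003/0.007 per cycle;
mortality per cycle 0.018 (thrombosis), 0.26 (leukemia), 0.021
(myelofibrosis). Alternative sources per transition (2·2·3 progression,
2·5·3 mortality) define the 360-combination scenario space.

## Synthetic inputs and what they do (not) represent

**Life table.** Background mortality expects any HMD-style `age,qx` (or
`age,mx`) period life table. The shipped synthetic table is a
Gompertz–Makeham hazard h(age) = a·e^(b·age) + c with b = 0.097/year and
c = 3·10⁻⁴/year (typical adult log-slope and background for a low-mortality
European population) and a calibrated by root-finding so that the 20-year
restricted mean survival from age 57 equals 18.5 life-years, the
general-population comparator of the reference analysis. A single unisex
table is used; age advances 0.25 y per cycle with integer-age floor lookup,
the standard period-table granularity. The synthetic table reproduces the
comparator RMST by construction, not Swedish mortality at every age; results
driven by the *shape* of old-age mortality beyond the calibrated window
should use a real table.

**JAK2 trajectory.** The trial's burden figure is not published numerically,
so the generator emulates it: the cohort mean burden declines linearly from
42.8% (the published baseline) to a plateau at week 156, constant
thereafter (nothing is observed beyond three years, so constancy is the
conservative extension). The mean is mapped to the proportion ≥ 50% through
a Normal cross-sectional burden distribution with σ = 20 percentage points,
a dispersion consistent with the wide burden ranges seen across PV cohorts
(31–61% of patients above the threshold in the validation studies). The
plateau mean (37%) and σ were calibrated once against the published
base-case 20-year outcomes (AL 3.98%, MF 11.88%, thrombosis 30.40%, OS
16.6 LY); the shipped defaults reproduce them to within ~1 pp and 0.1 LY.
A proportion-space generator (`synthesize_trajectory`) is also provided for
trajectories supplied directly as proportions. What the synthetic
trajectory cannot capture: non-monotone burden dynamics (e.g. response
followed by relapse) and any burden drift after year three — passing tests
certify the machinery under the emulated conditions, not the true trial
trajectory.

**Study-baseline adjustment.** To compare with an observed cohort, the
starting age is set to the study's median age and the mean-burden path is
rescaled multiplicatively so its baseline equals the study's baseline mean
burden; proportions are then recomputed through the Normal model, so the
proportion ≥ 50% responds nonlinearly to the shift. Studies reporting a
proportion above 50% instead of a mean burden are inverted through the same
model. This is the package's operationalisation of "equalizing" baselines;
it is a modeling choice, and trajectories lacking a mean-burden path fall
back to direct multiplicative scaling of the proportion, clamped to [0, 1].

**Digitized KM curves.** Consumed as `time_years,survival` CSV under the
right-continuous step convention. Digitization jitter up to 10⁻⁶ (small
upticks, values marginally above 1) is repaired by clipping and a cumulative
minimum; anything larger is rejected. Integration is exact rectangle
geometry over [t0, t1); no extrapolation beyond the last digitized point is
permitted, so curves must carry their follow-up endpoint. A
piecewise-exponential synthesiser provides self-contained stand-ins for
tests and examples.

## Numerical choices

- Survival output S(t) = 1 − dead(t) at cycle starts; restricted mean
  survival is the left Riemann sum Σ S(t)·Δt, making interval AUCs exactly
  additive. Undiscounted life-years throughout.
- The engine is pure cohort arithmetic: no randomness anywhere, traces are
  bit-reproducible. Randomness exists only in fixture generators, behind
  explicit seeds.
- Scenario sweeps memoise OS per full configuration fingerprint (risk-set
  values, age, trajectory identity, engine flags).
- Zero-length horizons, zero risks, qx = 0 and qx = 1 rows are all handled
  exactly (the certain-death year maps to a certain-death cycle).

## Known limitations

- Cohort-level reallocation cannot represent individual burden
  trajectories or burden-history-dependent risks.
- The published adjusted-model decade AUCs depend on the unpublished trial
  trajectory and digitized curves; with the synthetic trajectory the model
  reproduces them to ≈ 0.3 LY but not exactly, and the scenario-sweep OS
  ranges sit 0.15–0.25 LY above the published intervals at their lower
  endpoints.
- No costs, utilities or discounting: this is the epidemiological core of a
  cost-effectiveness model, not the economic layer.
- Deterministic scenario analysis only; no probabilistic sensitivity
  analysis over parameter distributions.
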