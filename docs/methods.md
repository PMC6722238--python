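# Methods

## Model structure

The model is a discrete-time (1-day cycle) individual-level
state-transition microsimulation over a 365-day horizon.  Each simulated
person occupies one of two states, *at risk* or *ongoing RTI*.  Onset is
exogenous — there is no person-to-person transmission — which matches the
consultation-rate interpretation of the incidence data the model is
calibrated to: an "episode" is a spell of influenza-like illness that
generates exactly one primary-care consultation.  Re-infection is allowed
after recovery; a person can have at most one ongoing episode.

Two intervention arms are evaluated on the same cohort: generalized
probiotic intake and no intake.  A third uptake level (4.4%, the
estimated current US intake composed of 1.6% supplement users and the
36/64 supplement/food market split) is available as a scenario toggle
that dilutes the effects to a Bernoulli subset of users.

## Synthetic cohort

The default cohort is `round(329,256,000 × 1/1,000) = 329,256` persons.
Ages are drawn from a banded US-like distribution whose 0–15 mass is
fixed at 19.81%; gender is generated for demographic fidelity but drives
no hazard or cost.  Marginal prevalences: 53.70% unvaccinated, 12.50%
active smokers (apportioned over ages ≥ 13), 26.59% passive smokers
(drawn among non-active smokers; the two are mutually exclusive), 95%
school enrollment among ages 1–15, 58% employment among ages 16+, and a
3% nursing-home rate among non-employed 65+.  Only marginals are
published, so attributes are independent given age apart from the smoker
exclusivity rule.

"Shared indoor environment" is the union of school enrollment,
shared-office work and nursing-home residence.  Because the published
composite prevalence (53.19%) is *smaller* than school enrollment plus
total employment, the shared-office flag is a configurable fraction of
the employed (default 0.7591, solved so the composite hits 53.19%).
Employment itself stays at 0.58 because the absenteeism totals depend on
it.  This is the only reading that reconciles the published composite
prevalence with the published missed-work-day totals.

## Hazard and calibration

The daily onset hazard of person *i* on day *d* is

    h_i(d) = λ · 365 · w(d) · r_i,     P(onset) = 1 − exp(−h_i(d)),

with `w(d)` a seasonal profile (default: a von-Mises-shaped winter peak
at day 35 with concentration 2; the published weekly consultation curve
is not reproduced, and the calibration absorbs the shape — headline
reductions under a flat profile differ by well under half a percentage
point).  `r_i` multiplies: the child/adult incidence ratio (default
2.85, the value implied by children being 19.81% of the cohort but
≈ 41.3% of avoided RTI days), the vaccinated rate ratio, and — only when
risk-factor effects are enabled — passive smoking RR 1.15, school RR 1.22
and shared-office/nursing-home RR 1.07.

**The base case excludes the risk-factor effects.**  The published
base-case tables imply control-arm mean durations of exactly 7.4 and
8.82 days (no smoking uplift) and a child avoided-day share of exactly
the value the 2.85 ratio produces without school/office rate ratios; the
risk factors enter the subgroup analyses only.  The `rtisim subgroups`
command therefore enables them by default, while `simulate` does not.

Two constants are calibrated: `λ`, so the expected control-arm episode
count equals 24,671 scaled to the cohort size, and the vaccinated rate
ratio ρ, so the expected unvaccinated share of episodes equals 0.554
(the value implied twice over by the published episode tables;
analytically ρ = (0.537/0.554 − 0.537)/0.463 ≈ 0.934).  The expectation
is computed by a deterministic renewal recursion over person types
(unique combinations of relative rate, mean duration and vaccination):
daily onset mass leaves the at-risk pool and returns according to the
duration distribution's survival function, which accounts for the
at-risk time lost to ongoing episodes.  Both parameters are solved by
nested Brent root-finding; residuals above 0.5% raise a calibration
error.  Calibration is expectation-based, not stochastic, so it is
deterministic given the cohort.

## Durations, resources, absence

Episode durations are continuous gamma draws rescaled to the person's
mean, with coefficient of variation 0.5 (a dispersion choice — the
sources publish means only; mild right skew, essentially no mass below
the 0.5-day floor) and a 0.5-day minimum.  Because the gamma family is
closed under scaling and draws are inverse-CDF transforms of shared
uniforms, a mean effect expressed as a multiplier moves every paired
draw by exactly that factor: the duration effects −0.77/7.4 and
−1.89/8.82 are reproduced exactly in the paired day totals.  Duration
effects are applied multiplicatively (1 − reduction/mean), not by
subtraction, so durations stay positive.

Per episode: one PCP visit (always), an antibiotic course with
probability 0.29 (times RR 0.65 in the probiotic arm where applicable),
other prescription medication with probability 0.5662 (no probiotic
effect).  Work absence is two-part: any-absence Bernoulli (42%
employees, 18% children) and a gamma conditional amount matched to the
published mean (SD) — 1.7 (5.1) and 0.5 (1.5) days — whose coefficient
of variation 3 is taken from those numbers.  Children's missed days
represent caregiver work loss and are costed at the same 217.92 USD/day.
The probiotic absence reductions are the standardized mean difference
0.17 times the published SDs, rounded half-up to two decimals (0.87 and
0.26 days), applied as conditional-mean multipliers to all episodes in
both scenarios: this unrestricted application is the only one consistent
with the published missed-work-day reductions, even though the other
Cochrane effects are restricted to the unvaccinated.

Episodes with onset inside the horizon contribute their full sampled
duration even when they extend past day 365; with ~7–9-day means the
resulting bias is below half a percent.

## Pairing design (common random numbers)

Every random decision is a pure function of (seed, stream, person,
day-or-episode): a splitmix64-based counter RNG replaces stateful
generators.  Both arms share one uniform per person-day — the control
arm onsets when u < p_control, the probiotic arm when u < p_probiotic ≤
p_control — and one uniform per (person, episode, resource).  The two
arms additionally share the control arm's renewal clock: an episode
suppressed or shortened in the probiotic arm does not alter the at-risk
schedule.  Consequences: probiotic episodes are an exact subset of
control episodes; paired durations differ by exactly the intended
factor; an identity effect set reproduces the control arm bit for bit;
and a single paired run at the full sample rate recovers the published
percentages to a fraction of a point.  The cost is a small counterfactual
bias (a truly independent probiotic arm would regain ≈ hazard ×
duration-change extra at-risk days per episode, ~0.03% of episodes at
the default parameters), far below replicate noise and accepted in
exchange for exact pairing.

## Costing

Payer: 74.16 USD per consultation, 26.59 USD per other-medication use,
and age-specific antibiotic course costs (2.95 USD ages 0–14, 3.54 USD
ages 15+ — the values that reproduce the published payer savings; the
alternative 6.49 USD amoxicillin price can be configured).  Copayments:
25 USD consultation, 11 USD other medication, none for antibiotics.
Societal = payer + copayment + productivity.  No discounting (one-year
horizon); inpatient care, OTC medication and the probiotic product cost
are out of scope.  National projection is an exact ×1,000.

## Analyses

* **Outcome table** — probiotic/control totals, absolute and percent
  differences for episodes, days, antibiotic courses, missed work days.
* **Subgroup attribution** — paired per-person differences in RTI days
  and societal cost, summed over subgroup flags (children, smokers,
  shared-indoor, unvaccinated); shares of a partition sum to 100%.
  Exact published subgroup percentages for the smoking/shared-indoor rows
  depend on unpublished age-specific incidence inputs and are validated
  directionally only.
* **One-way sensitivity** — each parameter moved to its published
  lower/upper bound, others at base, re-run under the base seed so
  parameter effects are not confounded with Monte-Carlo noise; reports
  avoided RTI days (sample scale) and societal savings (national scale).
  The PCP fee range is applied to the payer share with the copayment
  fixed.
* **Convergence** — mean and coefficient of variation of headline
  outcomes across replicate seeds at increasing sample rates; the paired
  design keeps the CV of the day reduction below 2% at the 1/1,000 rate.
* **Oracle** — closed-form expected reductions and savings (mixtures of
  kept-fractions and per-episode multipliers over the
  vaccinated/unvaccinated groups), used as an independent validation of
  the engine.  The closed forms ignore second-order effects (at-risk
  depletion, the duration floor), which shift results by well under one
  percentage point at the default parameters.

## What the synthetic cohort does and does not show

The generator reproduces marginal prevalences and the calibrated episode
process, not real-world correlation structure (household clustering,
socio-economic gradients, age-specific vaccination or employment), no
within-season waning or immunity, and no transmission dynamics.  Tests
passing on this cohort demonstrate that the model mechanics and
parameter arithmetic reproduce the published results under the published
assumptions — not that those assumptions describe any particular real
population.

## Numerical notes and limitations

* Problem sizes: unit tests run 1/10,000-scale cohorts (~33k persons);
  end-to-end checks run the full 1/1,000 sample with five replicate
  seeds, which the vectorized engine completes in seconds per run.
* The missed-work-day totals inherit the heavy tail of the absence
  distribution (CV 3); they are the noisiest outputs and are reported as
  5-seed averages.  The published Cochrane missed-day reduction
  (−60.50%) is about 1.1 pp stronger than the value implied jointly by
  the published episode reduction and the absence parameters (−59.4%);
  the model reproduces the latter.
* The vaccinated rate ratio is a single aggregate constant, not
  age-specific vaccine effectiveness; 0.554 is a derived calibration
  anchor, configurable.
* Whether nursing-home residents carry the shared-office rate ratio is
  an assumption (they do, RR 1.07).
* Antibiotic-course differences are binomially thinned per episode, so
  their replicate CV (~2.5% at full scale) does not shrink with cohort
  size under a fixed number of episodes.
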