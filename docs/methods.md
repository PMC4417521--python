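# Methods

This note records the model behind `crcisim`, the defaults and why they
were chosen, and what the simulation does and does not capture.

## The outcome

The Composite Referral Completion Indicator (CRCI) of a household is the
number of preventive services taken up by its members during a 1-year
study period divided by the number they were eligible for, counting a
service once per eligible member. Denominator zero (nobody eligible for
anything) makes the score undefined, not zero; such households are
excluded from means and SDs but re-enter sample-size arithmetic through
the valid fraction *v*, because a trial recruiting households cannot know
in advance which will have a defined score.

## Household synthesis

The population generator is driven entirely by a JSON demographic
specification: 20 census household types, each with a prevalence and a
composition rule. Sampling is type-first — one categorical draw per
household — followed by member-by-member composition; no iterative
proportional fitting is attempted.

Composition rules use a small vocabulary (`single`, `couple`,
`lone_parent`, `group`, plus optional dependent children, non-dependent
children and extra adults). Where only band-level structure is published,
within-band detail follows simple conventions:

- exact ages are uniform within bands;
- partner age = reference age + a discrete symmetric triangular gap
  (mode 0, range ±10 y);
- parent age = youngest child's age + mother's age at birth, uniform
  20–40 y;
- sibling spacing uniform 1–4 y, capped at the dependent-child age limit;
- dependent children are modelled at ages 0–17 (16–17 standing in for
  dependent 16–18-year-olds in education); non-dependent children living
  with parents at 16–34;
- household size is capped at 8; the rare composition that violates a
  type's age constraint (e.g. an all-elderly draw for a "not all 65 plus"
  type) is rejection-sampled.

The shipped default specification is calibrated so that (a) household-type
prevalences match the published England-and-Wales distribution exactly
(the printed column sums to 100.05% after rounding; the residual "Other
households (not all 65 plus)" category absorbs the 0.05 pp excess), and
(b) the simulated age/sex marginals sit within 2 percentage points of each
published band share at n = 20,000 (largest deviation ≈ 1 pp, women 75+).
The internal composition of student and "other" households is not
published; the rules for them are documented guesses flagged in the
fixture file.

Risk-factor prevalences (smoking among 16+, diabetes among 13+, an extra
at-risk-for-influenza factor at all ages, pregnancy among childbearing-age
women) are set so the simulated population shares reproduce the published
ones: smokers 19.0%, diabetics 2.8%, at-risk 4.5%, pregnant women 1.3% of
individuals. Pregnancy uses a constant hazard among female partners in
couple households (11.8%) plus a small teenage allowance (0.8%);
gestational timing is ignored. Diabetes always implies the at-risk flag.

## Service eligibility

The registry mirrors the published NHS-style schedule. Services without a
published uptake rate carry estimated defaults, flagged `estimated` in the
registry file and freely overridable: childhood seasonal influenza 0.45
(typical childhood programme uptake), rotavirus 0.94 (analogous infant
programme), varicella/zoster 0.60 (analogous older-adult programme).
Chlamydia screening is carried in the registry but excluded from the
score, since its records are confidential and unavailable from routine
data; it never generates eligibility records.

For a *k*-yearly programme the probability that a band member is due the
service in a single year is

    p = f_new + (1 − f_new) · [ 1/k + (1 − 1/k)(1 − r) ]

where `f_new = 1/(band width in years)` is the fraction newly entering the
band (all due) and the `(1 − r)` term returns previous non-attenders to
the pool. Inclusion is a Bernoulli draw at *p*. The influenza services
form an exclusion group — age-based flu takes precedence over pregnancy
flu, which takes precedence over at-risk flu (the at-risk service is also
age-capped at 64) — so nobody is counted due two flu vaccinations.
Multi-dose infant schedules are one eligibility unit each, matching how
their uptake rates are reported. The study period is fixed at 1 year; the
period parameter exists for extension but only 1 is exercised.

## Uptake scenarios

Control-arm uptake of each eligibility slot is Bernoulli(*r*). An
intervention converting a fraction *e* of forgone services uses
`r + e(1 − r)`. Two sensitivity modes:

- **Risk clustering "high"**: smoking, diabetes and the extra at-risk
  factor become all-or-none per household, with the household-level
  probability equal to the per-person prevalence so every marginal is
  preserved — the most extreme within-household concordance consistent
  with the stated marginals. Pregnancy stays per-person.
- **Compliance clustering "high"**: half of households are generally
  adherent (`r → r + 0.99(1 − r)`) and half generally non-adherent
  (`r → r − 0.99(1 − r)`, floored at 0, with the adherent rate capped at
  `min(1, 2r − r_non)`). With this construction the 50/50 mixture mean
  equals *r* exactly for every *r* in [0, 1] — the cap never binds because
  `r + 0.99(1 − r) ≤ 1` — so the clamping deficit the pipeline reports is
  identically zero; it is retained as a safeguard for user-supplied
  variants of the transform. Household labels are drawn once per
  household, independent of type, and shared between arms.

Both arms of a scenario run score the *same* synthesized population and
eligibility table; only the uptake draws differ, via separate child
streams of one root seed (`numpy` `SeedSequence` spawn keys per stage), so
changing the effect size never perturbs demographics and the paired
design reduces Monte-Carlo noise in the arm difference. A zero-effect
"intervention" reuses the control draws, making the degenerate
zero-difference case exact.

## Sample size

Means are compared with the normal-approximation formula
`n_valid = (z_{1−α/2} + z_{power})² (σ_c² + σ_i²) / Δ²` (variance
convention: sum of the two arms' variances; no continuity or *t*
correction), then inflated by `1/v` and, for cluster randomization, by
`1 + (m − 1)ρ`. Defaults: α = 0.05 two-sided, power 0.90, m = 100
households per CHW. SDs are sample SDs (divisor n − 1) over defined
scores. Reported sizes are rounded half-up to the nearest 10, the
convention the published tables follow.

## Problem sizes and numerical checks

Headline analyses use 20,000 households (≈ 45,000 people, ≈ 49,000
eligibility records; a full paired-arm run takes a few seconds). The test
suite verifies the stochastic machinery against an exact oracle: the
per-household score's expectation and variance are computed by
enumerating the Poisson-binomial distribution of the taken count, and
10,000 replicate uptake draws on a fixed household fixture must agree
within 3 standard errors. Per-service empirical uptake must recover the
configured rates within 3 binomial SEs at n = 20,000, and simulated
household-type frequencies are checked with per-type 3-SE bands plus a
pooled chi-square goodness-of-fit test (a fixed seed across 20
simultaneous bands otherwise over-rejects on rare types).

## What the generator does and does not emulate

It reproduces the published household-type mix, approximate age/sex
marginals, risk-factor marginals and service uptake rates — enough to
characterise the CRCI's distribution and its sensitivity to clustering
assumptions. It does **not** model: geography or deprivation gradients
(supply a custom specification for, e.g., a deprived-area type mix);
household change over time (members moving in or out, births during the
study); correlation of uptake across services within a person beyond
household compliance; real vaccination calendars, catch-up doses or flu
seasons; or behavioural responses. Passing tests therefore show internal
consistency and calibration to the published aggregate structure, not
fidelity to any particular real community.

Simulated control-arm summaries land near, not on, the published values
(mean 0.54–0.55 vs 0.56; valid fraction 87.3% vs 88.3%): the underlying
census composition tables behind the published simulation are not
printed, so the default fixture approximates them, and several service
rates are estimates. The sensitivity directions and magnitudes
(high risk clustering: valid fraction → ≈ 84.8%, sample sizes up
≈ 17–25%; compliance clustering: SD 0.36 → 0.41 with unchanged mean)
reproduce the published pattern.
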