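# Methods

This note records the models the package implements, the defaults it
ships, and why; what the synthetic data do and do not emulate; and the
numerical choices that matter for reproducing its behaviour.

## The design being emulated

Seven double-blind randomised trials of modified infant formulas
(1993–2001, five English centres) are "reactivated": their retained
identifiers are linked to a national pupil register, and the randomised
comparison is re-analysed with school examinations at ages 11 and 16 as
cognitive endpoints. The package reproduces this design as an
executable pipeline. The trial design tables in `trials.py` carry, per
trial: per-arm randomised counts (totalling 1763), the per-arm counts
linked to an exam record in the original study (totalling 1607, i.e.
91.2%), the infant population (preterm, term small-for-gestational-age,
term), recruitment centres, the randomisation period, permitted
permuted-block sizes, and the mean number of identifier contacts per
participant. The linked per-arm counts are the analysable sample sizes:
they drive the minimum-detectable-effect table and the accounting
checks. The NUCLEOT cohort was randomised ~7 years after the others and
had not reached GCSE age inside the register window, so its age-16
outcomes are structurally missing (cells suppressed, never invented).

The closed-form MDES, (z₀.₉₇₅ + z₀.₈)·√(1/n₁+1/n₂), reproduces the
published detectable differences for IRONT (0.32), LCPUFAT (0.33),
PALMT (0.41) and LCPUFAP (0.43) from the linked per-arm counts. For NEP
and NETSGA the published values (0.37, 0.33) are not recoverable from
any printed counts (the closed form gives 0.38 and 0.34); the exact
analysable n behind them was never printed, so those two are documented
here rather than asserted.

## Synthetic data world

**Latent-ability model.** Each child carries one latent score

  s = β·x − δ(population) + τ·1[modified arm] + ε,  ε ~ N(0, 0.94²)

with covariate effects β (maternal degree +0.30, maternal smoking
−0.15, male −0.10, +0.05 per kg birth weight, +0.02 per gestational
week, small centre effects) chosen as modest, literature-plausible
associations with academic attainment; a non-negative deficit δ
(preterm 0.45 SD, term-SGA 0.25 SD) reproducing the pattern of lower
raw grades in the preterm/SGA cohorts; and an injectable per-trial arm
effect τ in SD units, zero by default — the default generator is a null
model. Background register pupils draw s ~ N(0,1).

**Grades.** A per-subject score s + N(0, 0.30²) is discretised into
A*–G/U by thresholds set at the normal quantiles of a fixed national
grade distribution (A* 5%, A 10%, B 15%, C 25%, D 15%, E 12%, F 9%,
G 5%, U 4%, bottom-up cumulated). Grade inflation is emulated by
shifting the effective score +0.01 SD per exam year after 2008; the
per-year national mean and SD used for external standardisation are
computed analytically from the same thresholds, so simulated register
marginals match the reference by construction (the generator's z-mean
check at n = 10 000 uses tolerance |mean| < 0.05). Age-11 scores are
50 + 15·(s + N(0, 0.45²)) clipped to [0, 100]. Special-educational-needs
support is Bernoulli with logit −2.0 − 1.3·s.

**Cohort construction.** Trial covariates are parametric
approximations to the baseline tables: truncated normals for birth
weight, gestational age and maternal age (truncated at the printed
ranges), Bernoulli sex/smoking/degree at the printed proportions.
Allocation uses permuted blocks of randomly chosen even length
(default {2,4,6}), stratified by centre, filled so the configured
per-arm totals are met exactly. Twin pairs (5% of participants in
preterm trials, 1% in term trials — not printed, configurable) share
date of birth, surname, address and maternal covariates, with forced
distinct forenames. Infant deaths (preterm 3%, term 0.5% — not printed)
occur before school entry: the deceased claim no register pupil and
carry no outcomes.

Participants claim pupils from the pre-generated background register:
the claimed pupil's identity fields and school outcomes are rewritten
from the participant. This keeps the register-first data flow (and the
false-candidate population) while letting arm effects reach exam
results.

**Error model** (per-participant probabilities, all configurable;
zero model = identity): transcription typo in a name 0.05, surname
change after the trial 0.03, unrecorded postcode move 0.05 (half of
moves land in a neighbouring authority, exercising that agreement
level), date-of-birth digit error 0.01, missing field 0.02, never in
the register (private schooling/emigration) 0.05. With deaths these
defaults put the simulated link rate in the low-90s percent range,
deliberately near the real study's accounting.

**What the synthetic world does not emulate:** real name frequency
distributions and their ethnic/geographic structure, real postcode
geography (a 1000-postcode, 50-authority synthetic universe with a grid
neighbour graph stands in), informative register absence, school-level
clustering, and subject-level psychometrics. Passing tests therefore
demonstrate the correctness and calibration of the *machinery* under a
known generative model, not linkage performance on real registers.

## Linkage

The linker follows the Fellegi–Sunter model. m-probabilities default to
closed-form functions of the error model (e.g. P(surname exact | match)
= 1 − typo/2 − change); u-probabilities default to frequency estimates
for the synthetic identifier universe. Both are overridable; no EM
estimation is attempted — with a declared error model the weights are
known, and estimating them is a separate problem.

Numerical/decision choices: partial string agreement is normalised
edit-distance similarity ≥ 0.8 (edlib); date-of-birth partial agreement
is exactly one differing component; each field is compared against the
best-aligning pair of chronology entries (histories are deduplicated
consecutive states, date-ordered). Candidates are capped at four per
participant by a provisional exact-agreement count with pupil-id
tie-breaks for determinism. Assignment is greedy one-to-one by
descending score, ties broken by more exact-level fields then lowest
pupil id. The acceptance threshold (default 0: link iff the pair is
likelier a match than a non-match) is applied *after* assignment, so
the linked set at a higher threshold is a subset of that at a lower
one and threshold sweeps trace an exactly nested precision/recall
trade-off. Death exclusion is applied before assignment. One-to-one
assignment is enforced (and asserted post-hoc); whether the original
study enforced it is unknowable from outside, but duplicate pupil
claims are incoherent under the design.

## Outcomes

GCSE letters map to the 8-point pre-2017 scale; internal
standardisation uses the sample SD (n−1) over linked, outcome-complete,
surviving participants of the trial with both arms pooled (the
pooled-arms choice is declared; a control-arm-only reference would
rescale, not re-centre, the contrast). Standardisation precedes
imputation, so imputation operates on the z scale. The attainment
indicator requires ≥5 subjects at ≥C including both mathematics and
English.

## Inference

Chained imputation visits covariates first, then outcomes, each in
ascending missingness order, for 10 burn-in iterations per chain;
chains initialise from observed-data draws; linear models impute with
posterior-predictive draws (σ² from a scaled inverse-χ², coefficients
from their normal posterior), binary models with Bernoulli draws under
a normal approximation to the logistic posterior (light ridge for
stability). m = 15 by default. Deceased participants are excluded
before imputation and excluded rows never reappear. A variable with no
observed values is left missing under automatic selection and raises
when requested explicitly.

Fits use statsmodels OLS/Logit with the HC1 sandwich (n/(n−k)
small-sample scaling) — HC1 chosen as the common default of the
statistical environments this design is usually run in. Collinear or
constant design columns (e.g. the centre dummy of a single-centre
trial) are dropped with a log line, assessed on complete rows.
Logistic separation or single-class outcomes mark the cell
non-estimable rather than reporting an unstable estimate. Rubin
pooling uses the normal reference (not Barnard–Rubin t), matching
1.96-style intervals at m = 15 and n in the hundreds; B is exactly
zero when all imputations agree, so zero-missingness data reproduce
complete-case results to machine precision. No multiple-testing
correction is applied across trials or outcomes, mirroring per-trial
reporting; readers should treat the matrix accordingly.

## Problem sizes and calibration

The test suite and acceptance script use a background register of
4000 pupils for full seven-trial worlds and 1200 for single-trial
Monte-Carlo replicates, sizes at which the candidate space still
contains realistic false matches. Calibration uses 500 end-to-end
replicates of an IRONT-like trial (327 randomised): under τ = 0 the
MI-adjusted primary analysis should reject at ~5% and cover at ~95%
(HC1 with ~300 observations is known to be very slightly
anti-conservative, which the acceptance bands accommodate); under
τ = 0.33 — the MDES at the IRONT analysable n — empirical power should
sit near 80% by construction. Grade discretisation attenuates an
injected latent effect by a few percent, and covariate adjustment
recovers a similar amount; both effects are visible in the recovered
estimates and roughly cancel at these settings.

## Known limitations

- u-probabilities are fixed defaults, not estimated from data; linkage
  quality metrics on other identifier universes require re-deriving
  them.
- The chained-equations sampler assumes linear/logistic conditionals;
  no predictive-mean matching.
- The report's benefit verdicts are per-cell CI statements without
  multiplicity control.
- Dates of birth are perturbed only into valid calendar dates with
  single-component errors; impossible dates are flagged upstream, not
  modelled.
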