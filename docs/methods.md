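# Methods

This note documents the models, the synthetic-data generator, the numerical
machinery and the open design choices behind `contact_triad`.

## Survey structure and derived covariates

The unit of observation is the *contact event*: one diary entry describing
either an individual or a group met face-to-face on the prior day, with a
group size (1 for individuals), setting (home / work / school / social /
other), touch indicator, contact frequency (<1, 1–3, 4+ per week) and
duration (<10, 10–59, 60+ minutes).  A participant-visit's **total reported
contacts** is the sum of event group sizes; events flagged as *repeats*
re-list people already counted elsewhere and contribute zero to the total
(they keep their attributes for event-level analyses, and are excluded from
triangle enumeration because the dyads they would generate already exist).

Participant age is collapsed to bands 2–15, eight 10-year bands to 75, and
76+; occupation to employed / student / other (other = children not in
school, unemployed, retired, homemakers).  Contact age uses the reported
band when present, otherwise bins a numeric age guess, otherwise is unknown.
Population density enters as log10 of the household's density at the first
analysed visit, so effects read as "per 10-fold increase".  Contact
*intimacy* is weekly minutes = frequency midpoint × duration midpoint.  The
open-ended bins have no defined midpoint; the defaults close them at
plausible caps (<1/wk → 0.5, 4+/wk → 5 contacts/week; 60+ min → 90 min).
Only the ordering of intimacy scores matters downstream, and that is
insensitive to the caps; the caps are configurable via `MidpointConfig`.

Triangle certainty responses (yes / probably yes / probably no / no) are
dichotomized at one of three cutoffs; the main analysis counts "yes" and
"probably yes" as affirmative, the other cutoffs support sensitivity
analyses.  Missing covariates are handled by complete-case exclusion at the
design-building step.

## Count model

For participant-visit *i*:

    y_i ~ Poisson(mu_i)
    log mu_i = x_i' beta + gamma_visit(i) + u_loc(i) + u_hh(i) + u_part(i) + e_i

with independent normal random effects at the four levels.  The
observation-level effect `e_i` makes the marginal count a lognormal-Poisson
(variance > mean): this is the generative realization of what survey reports
call quasi-Poisson regression, chosen over quasi-likelihood point estimation
because it yields a proper likelihood for Bayesian fitting and WAIC.
Household size enters as log(size), centred; density as centred log10.  The
"extra-household" outcome drops home-setting events only — contacts made on
transport or while shopping remain extra-household.

Priors: Normal(0, 5²) on the intercept, Normal(0, 2.5²) on slopes (covariates
are centred or near-unit-scale dummies), half-Normal(0, 1) on all
random-effect SDs.  Random effects are non-centred (`u = sigma * z`,
`z ~ N(0,1)`) and SDs are sampled on the log scale; both choices remove the
funnel geometry that otherwise defeats gradient-based samplers when SDs are
small.

## Triangle model

A potential triangle whose two contact events have group sizes g1, g2 stands
for m = g1·g2 *underlying* person-level triangles.  With per-underlying-
triangle connection probability p = logit⁻¹(η), the observed "any connected"
indicator has the **any-of-m likelihood**

    y = 1:  log P = log(1 − (1−p)^m)
    y = 0:  log P = m · log(1−p)

computed via `log1p`/`log1mexp` so it is finite over p ∈ [1e-12, 1−1e-12]
(the clamp bounds guard the logs; they are documented and tested) and for m
up to 10⁴ and beyond.  The gradient of the y = 1 branch is evaluated in log
space, which keeps it finite in the η → −∞ limit (where the slope tends
to 1).

Three strictly nested fixed-effect sets are supported:

* `participant_only` — age group, sex, log household size, occupation,
  log10 density, visit;
* `individual_contact` — adds the characteristics of the two contact
  events.  Because the pair is unordered, categorical attributes enter
  **symmetrically as per-pair counts** (0/1/2 events at each non-reference
  level; references: social setting, <1/wk, <10 min), plus a count of
  touch events, a pair-level any-group indicator and log m.  The count
  coding was chosen over per-slot dummies so the design is invariant to
  which event is labelled primary; log m (rather than raw m) keeps the
  covariate near unit scale across four orders of magnitude of m.
* `shared_contact` — adds shared-attribute indicators: same setting, same
  frequency, same duration, both involve touch.  The indicator set is the
  natural closure of the per-contact attributes; it is configurable in the
  sense that the design matrix is an ordinary column list.

Random effects at location / household / participant; priors and
parameterization as in the count model.  Before fitting, observations in
the top 0.5% of m are trimmed (pooled across visits by default, per-visit by
flag): the threshold is the linear-interpolation empirical 99.5th
percentile and rows **strictly above** it are removed, so ties at the
threshold are retained.  Re-trimming the retained table is a no-op whenever
the surviving upper tail is tied at the threshold (always true in the
degenerate constructions used to validate the rule; for continuous-like
tails a recomputed percentile could trim further, which is why the retained
threshold semantics are documented here).

Enumeration conventions: the two primaries are asked against every other
event *including each other*, so the primary–primary dyad is asked twice;
it is collapsed to a single triangle keyed on the lower event id.  A
participant-visit with E ≥ 2 eligible events and 2 primaries therefore
yields 2(E−2) + 1 potential triangles.

`stratified_probability` provides the descriptive analogue: per-stratum
maximum-likelihood p under the any-of-m likelihood with stratum intercepts
only (no hierarchy).  With constant m it inverts in closed form
(p̂ = 1 − ((n−k)/n)^{1/m}), which the tests use as an oracle.

## Sampling and diagnostics

No probabilistic-programming backend is used: both posteriors are sampled
with an in-package No-U-Turn sampler (`contact_triad._nuts`) — multinomial
trajectory sampling, dual-averaging step-size adaptation to a 0.8 target
acceptance, and diagonal mass-matrix estimation over expanding warmup
windows — driven by hand-derived analytic gradients.  The sampler is
validated in the test suite against exact Gaussian and conjugate posteriors,
gradient code against central finite differences, and the triangle model
against an independently coded hierarchical Bernoulli-logistic fit on m ≡ 1
data.  Defaults mirror the survey-analysis protocol: 4 chains × 2000
iterations, first 1000 discarded as warm-up; a reduced preset (2 × 500/250,
tree depth ≤ 8) is used for the small synthetic fits in the test suite.

Convergence is assessed with rank-normalized split R-hat and bulk/tail
effective sample sizes (computed by arviz behind the package's
`gelman_rubin` / `effective_sample_size` surface), with an adequacy flag at
ESS ≥ 200.  Degenerate constant chains are reported as R-hat 1 and ESS =
number of chains, flagged.  Model comparison uses WAIC computed from the
pointwise log-likelihood matrix with log-sum-exp stabilization:
lppd = Σ_i log mean_s exp(ll_is), p_waic = Σ_i var_s(ll_is) (sample
variance, ddof = 1 per the loo/BDA convention; arviz uses ddof = 0, and the
cross-check test converts between the two), and waic = −2(lppd − p_waic)
exactly.  Ties are broken by specification name for stable output.
Estimates are posterior means; intervals are central 95% quantiles of the
draws, exponentiated for relative rates / odds ratios.

## Synthetic-data generator

The generator is the package's test bed: it draws survey tables from the
same model families the fitters assume, with every random quantity recorded
as ground truth.

* **Population**: `n_locations` communities (default 40) on an exactly
  monotone density transect spanning 100–10,000 people/km² (sign
  configurable), `households_per_location` (default 20) households with
  Poisson-distributed sizes around 4, per-resident enrolment probability
  0.65, ages 2–90 with adult-heavy band weights, occupation conditional on
  age (students concentrated at ages 5–22, employment at 16–60, retirement
  after 60), and per-visit attendance 0.85 over visits 2–5.
* **Diaries**: totals drawn from the count model above (defaults: baseline
  10 daily contacts; age rate ratios dipping for young adults and falling
  to 0.60 at 76+; SDs 0.20 / 0.25 / 0.35 / 0.30 at location / household /
  participant / observation level), partitioned into events whose sizes are
  1 with probability 0.67 and otherwise 2 plus a negative-binomial excess
  (r = 0.4, mean 7) — a zero-truncated heavy tail giving roughly a third of
  events as groups and a long upper tail, without copying any empirical
  distribution.  Event attributes (setting given occupation; frequency,
  duration, touch given setting) follow configurable probability tables
  with home/school contacts frequent, long and touch-heavy, and work/other
  contacts briefer and less frequent.  Repeat-flagged re-listings are added
  at rate 0.05 and never change totals.
* **Triangles**: two primaries drawn uniformly per participant-visit; each
  unordered pair receives one latent outcome, connected with probability
  1 − (1−p)^m where logit p carries the triangle truth (defaults: baseline
  p ≈ 0.18 at the reference; U-shaped age effects rising to OR 2.67 at
  76+; OR 0.57 per 10-fold density; same-setting OR 7.37; group OR 0.26;
  log-m OR 0.37; SDs 0.3 / 0.3 / 0.5).  The latent indicator maps to the
  4-level certainty scale with 10% softening of true yes → "probably yes"
  and true no → "probably no", so the certainty cutoffs are exercisable:
  under the main cutoff the dichotomized outcome equals the latent truth.

All three stages draw from fixed sub-streams of one seed, so tables can be
regenerated independently and reruns are bit-identical.

What the generator does **not** emulate: real geography beyond the monotone
transect; recall bias, proxy reporting for children, staff turnover between
visits, or any systematic misreporting beyond the symmetric certainty
softening; correlation between a participant's group sizes and their
covariates; household composition change across visits.  Passing tests
therefore demonstrate that the estimators recover the structure they assume
— calibration, identifiability, model selection — not robustness to the
measurement problems of real diary data.

## Problem sizes in the test suite

Recovery and model-selection tests run at deliberately small scale so the
whole suite is quick on a single core: coverage uses 20 replicates of a
4-community, 4-households-per-community, two-visit survey (≈ 60–90
participant-visits, ≈ 400–1000 potential triangles per replicate) with the
reduced MCMC preset; WAIC selection uses 10 replicates at 3 × 3 × 1 scale.
Credible-interval coverage is pooled over replicate × coefficient pairs and
required to reach 0.90 for a nominal 0.95 interval, the slack reflecting
the small replicate count.  At these sizes several weakly-informed
coefficients are prior-dominated, which is immaterial for calibration
checks (the prior covers the truth) and is why point-recovery assertions
are reserved for the strongly-informed effects.

## Known limitations

* The sampler is a straightforward NUTS implementation; it has no
  cross-chain adaptation, and very small random-effect SDs can still
  produce occasional divergences at reduced warmup lengths (reported in
  `PosteriorFit.meta`).  Raise `target_accept` or lengthen warmup if they
  appear at full scale.
* WAIC is the only comparison criterion implemented (no LOO-CV).
* The 4-level certainty scale is only dichotomized, never modelled as
  ordinal.
* Trimming thresholds are recomputed from whatever table is passed in; see
  the idempotence caveat above.
* `PosteriorFit` retains only the reported parameters (fixed effects and
  SDs); latent per-unit effects are used for the pointwise log-likelihood
  and dropped to bound memory.
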