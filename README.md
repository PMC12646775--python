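# contact-triad

Analysis of **first- and second-order social contact network structure**
from egocentric contact-diary surveys, of the kind used to parametrize
respiratory-pathogen transmission models.

Contact surveys routinely measure *first-order* structure — how many people
each participant met face-to-face the previous day (their degree).  This
package additionally estimates *second-order* structure: **local clustering**
(transitivity), the tendency of a participant's contacts to also know each
other, measured through a survey module that asks, for two randomly selected
"primary" contact events and every other reported contact, whether the pair
interacted in the prior week.  Each such question defines a *potential
contact triangle*.

It is a library for epidemiologists and infectious-disease modellers working
with diary data from cohorts in which participants are nested in households
nested in sampled communities, and in which contacts may be reported as
**groups** (one diary entry with a group size, e.g. everyone a cafeteria
worker serves).

## Models

**Daily contact counts** (first order).  For participant-visit $i$ the total
reported contacts $y_i$ (sum of event group sizes, repeats counted once)
follow an overdispersed Poisson:

$$y_i \sim \mathrm{Poisson}(\mu_i),\qquad
\log \mu_i = x_i'\beta + \gamma_{v(i)} + u_{\mathrm{loc}(i)} +
u_{\mathrm{hh}(i)} + u_{\mathrm{part}(i)} + e_i,$$

with normal random effects at location, household, participant and
observation level; $e_i$ makes the marginal a lognormal-Poisson and carries
the overdispersion.  Covariates: age group (reference 36–45), sex, log
household size, occupation class, $\log_{10}$ population density; visit is a
fixed effect.  Effects are reported as relative rates $e^\beta$.

**Triangle connectedness** (second order).  A potential triangle whose
primary and secondary events have group sizes $g_1, g_2$ stands for
$m = g_1 g_2$ underlying person-level triangles (two groups of 10 imply
100).  Each underlying triangle is connected independently with probability
$p = \mathrm{logit}^{-1}(\eta)$, but the survey only observes whether *any*
is, so the observation likelihood is the **any-of-m** form

$$P(y=1) = 1 - (1-p)^m, \qquad P(y=0) = (1-p)^m,$$

which reduces to ordinary Bernoulli-logistic at $m=1$.  $\eta$ carries the
same participant/household covariates plus, in three strictly nested
specifications, contact-event characteristics (setting, frequency, duration,
touch, group status, $\log m$) and shared-attribute indicators (same
setting, same frequency, same duration, both involve touch), with random
effects at location, household and participant level.  Observations in the
top 0.5% of $m$ are trimmed before fitting.  Specifications are compared by
WAIC; effects are reported as odds ratios.

Both models are fitted by MCMC (an in-package No-U-Turn sampler with
non-centred random effects; 4 chains × 2000 iterations, first 1000 warm-up,
by default) with rank-normalized split R-hat and bulk/tail ESS diagnostics.

## Worked example

`examples/` holds one short script per capability.  Fitting the nested
triangle models on a synthetic survey (`examples/fit_triangle_clustering.py`)
prints, for a 5-community, two-visit survey generated with the default truth:

```
941 potential triangles; 5 trimmed (top 0.5% by underlying-triangle count m)
29% reported connected

OR(same setting) = 13.9 [8.2, 23.6]
OR(group contact) = 0.24 [0.12, 0.43]

WAIC ranking (lower is better; Δ vs best):
             model        lppd    p_waic        waic     d_waic
    shared_contact -304.287677 49.960045  708.495443   0.000000
individual_contact -385.373190 39.427689  849.601756 141.106313
  participant_only -614.476709 67.870982 1364.695382 656.199939
```

Two contacts met in the same setting have sharply raised odds of knowing
each other (generating value OR ≈ 7.4; the interval is wide at this small
example size), group contacts lower the odds of connection (generating value
0.26), and WAIC correctly prefers the specification the data were generated
from.  `examples/fit_contact_counts.py` does the analogous run for daily
contact counts and prints relative rates next to their generating values.

A thin CLI mirrors the pipeline:

```bash
contact-triad simulate --seed 1 --out-dir survey
contact-triad fit-counts --data-dir survey --outcome all
contact-triad fit-triangles --data-dir survey --spec shared-contact \
    --certainty-cutoff probably-yes --trim-quantile 0.995
contact-triad compare --data-dir survey
contact-triad report --data-dir survey
```

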