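# Methods

## Problem and scope

`equilist` models the child-mortality impact of eliminating within-country
wealth inequality in health-intervention coverage. The unit of analysis is a
country-year birth cohort observed at two time points: a baseline year at
current national coverage and a scale-up year at top-wealth-quintile coverage.
Outcomes are neonatal (first month) and post-neonatal (1–59 months) deaths by
cause, their sum (under-five deaths), lives saved in total and per
intervention, and mortality-rate changes. Maternal deaths and stillbirths are
out of scope, as are nutrition-status risk-factor pathways (stunting, wasting,
breastfeeding patterns), herd effects, and multi-year demographic projection.

## Inequality ratios and their resolution

For intervention *i*, the raw inequality ratio is top-quintile coverage
divided by national coverage. Two values are kept deliberately distinct:

* **raw ratio** — unfloored, reported in `ratios.csv`; values below 1 mark
  pro-poor coverage (typical for mass-campaign commodities like bednets).
* **applied ratio** — max(raw, 1), used to build scenarios, so the
  counterfactual never lowers coverage.

Unmeasured interventions resolve through the catalog's channel structure:

* **direct** — survey-measured; if this survey lacks the indicator, the
  named backup's *own* ratio is used. Backup resolution is one level deep
  only: backups can name each other (improved sanitation ↔ home water
  connection), and chaining would make resolution order-dependent.
* **proxied** — adopts the source's resolved ratio (the source may itself
  have fallen back to its backup); failing that, the proxied item's own
  backup.
* **linked** — components of antenatal or childbirth care take the ratio —
  and, in the engine, the coverage — of their parent contact point.

Flooring happens once, after resolution, on the final applied value. A
top-quintile value missing while national is present counts as unavailable
and falls through to the backup. Unresolvable ratios are first-class
(`provenance=unavailable`): the intervention simply stays at baseline, logged.

## Scenarios

Baseline coverage is each non-linked intervention's national rate; the target
is baseline × applied ratio, capped at 1.0. The cap matters because a ratio
estimated from an older survey multiplies a newer national rate (or, via
proxies, a different intervention's rate) and can overshoot 100%. Modes:

* **full** — all 38 scale-up items move (proxied included);
* **limited** — only survey-measured interventions and their linked
  components move; proxied items stay at baseline. This is a conservative
  lower bound and, by construction, the limited scaled set is a subset of the
  full one, so limited lives saved can never exceed full.
* **single(id)** — one intervention moves; naming a contact point moves its
  whole linked bundle. Scaling a linked component alone is rejected, since
  its coverage has no independent observation — rank the parent bundle
  instead.

Contraceptive prevalence is scaled only where baseline total fertility
exceeds the replacement-level gate (2.33 children per woman); below it, the
model assumes no unmet need for limiting births that a coverage scale-up
would serve.

## The impact engine

Baseline deaths per (age band, cause) cell are
`D0 = births × rate/1000 × cause_fraction`, with under-five deaths equal to
neonatal + post-neonatal by construction. Each intervention removes the
fraction `E·AF·C` of a cell's deaths; interventions combine multiplicatively
into the residual `R(c) = Π (1 − E_i·AF_i·c_i)`. Because `D0` already embodies
baseline coverage, scenario deaths are normalized to baseline:

    D1 = D0 × (births1/births0) × R(c1)/R(c0)

Contraceptive scale-up acts as a pure birth-cohort scaling,
`births1 = births0 × (1 − u1·e)/(1 − u0·e)` with use-effectiveness `e` (0.9 by
default): at a two-time-point horizon the cohort simply shrinks, and no
age-structured projection is needed. Mortality rates are deaths divided by
the *scenario's own* births, so rate changes and death changes can differ
when fertility moves.

### Attribution without double-counting

Per cell, the fertility component `D0·(1 − births1/births0)` is credited to
contraception; the remaining savings are split across interventions in
proportion to their solo log-impacts
`w_i = ln[(1 − E_i·AF_i·c0_i)/(1 − E_i·AF_i·c1_i)] ≥ 0`. Log weights are the
natural additive decomposition of a multiplicative residual
(`ln R` is the sum of the `w_i`), which makes the rule order-independent and
exactly conservative — properties that sequential (peel-one-off-at-a-time)
attribution lacks. Zero-effect or unscaled interventions get weight 0 and
never receive attribution.

### Numerical guards

* `E·AF·C` must stay below 1 − 1e−12 (a residual of zero would make baseline
  normalization divide by zero); the shipped catalog keeps `E·AF < 1`.
* `u1·e ≥ 1` raises a model error (all fecund exposure removed).
* Scenario targets below baselines are rejected at construction; floating-
  point comparisons in invariants use 1e−12 slack.
* Ties in rankings and league tables break deterministically by intervention
  id.

## The intervention catalog

41 entries: 18 directly survey-measured indicators — three of which
(antenatal care, skilled birth attendant, facility delivery) are coverage-only
contact points that carry no effects and exist to drive linked components —
plus 14 linked components of antenatal/childbirth care and 9 proxied
interventions. Excluding the three contact points leaves 38 scale-up items
(contraception among them, acting through the fertility pathway only).

Effectiveness and affected-fraction values are shipped as a versioned YAML
data file with plausible magnitudes chosen so that each default cause has at
least one acting intervention and facility-based childbirth care carries the
largest neonatal impact. They are explicitly **non-authoritative** package
defaults: any substantive application should supply its own catalog via
`load_catalog`, which can also extend the cause lists.

## Synthetic survey generator

The generator emulates the statistical structure of wealth-disaggregated
household-survey compilations so the whole pipeline is testable without
microdata. Per country and intervention, quintile coverage follows a
logit-linear wealth gradient `c_q = expit(α + β(q − 3))`, the simplest
monotone model of wealth-graded access: α is uniform on the logit of the base
coverage range and β half-normal with scale `gradient_scale` (default 0.35,
putting implied top-quintile/national ratios in the 1.1–1.5 range typical of
measured MNCH indicators). Bednets get a flipped (pro-poor) gradient sign.
National coverage is the unweighted quintile mean, quintiles being population
fifths by definition.

Missingness (default 10%) blanks an intervention's five quintile columns
while keeping its national value: this mirrors the real data situation —
national coverage is known for every modelled intervention from programme
data, while a given survey may lack the wealth disaggregation — and it is the
pattern that actually exercises backup resolution (blanking the national
value too would leave nothing to scale). Proxied interventions get a
national value but never quintiles; linked components get no coverage row.

Cause-of-death fractions are Dirichlet draws centred on a typical high-burden
profile with total concentration 25 (symmetric Dirichlet would give injuries
the same weight as pneumonia); mortality rates, fertility, and (log) births
are uniform over low-income-country ranges. Defaults produce 98 countries.
Everything derives from one seed and is byte-reproducible.

What the generator does **not** emulate: survey design effects (clustering,
weights), sampling error in coverage estimates, correlation between
interventions within a country beyond the shared country intercept range, or
correlation between coverage and mortality levels. Passing tests therefore
demonstrate the pipeline's internal correctness and directional behavior
(e.g. full ≥ limited), not agreement with any real-world estimate.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: the
brute-force and property suites use 1000 random ≤3-intervention instances,
multi-country checks use 6–40 synthetic countries, and the acceptance script
uses the generator's default 98 countries — the full pipeline at that size
completes in about a second.

## Known limitations

* Effectiveness defaults are illustrative; absolute lives-saved magnitudes
  from the default catalog have no external validity.
* The multiplicative residual assumes independent intervention action within
  a cause; real co-delivered interventions overlap in recipients.
* Applying a possibly stale survey ratio to current national coverage
  overstates inequality where gaps have since narrowed (hence the
  `--min-survey-year` filter and the cap at 100%).
* Single-intervention rankings ignore interactions; their rows do not sum to
  the joint-scenario total, by design.
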