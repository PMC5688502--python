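# equilist

Equity analysis of child-health intervention coverage: what would happen to
under-five mortality if every household in a country had the intervention
coverage already enjoyed by the richest 20%?

In low-income, high-mortality-burden countries, coverage of maternal,
neonatal, and child-health (MNCH) interventions — facility delivery, vaccines,
oral rehydration solution, bednets, water and sanitation — is usually far
higher in the top wealth quintile (WQ) than in the country as a whole.
`equilist` turns quintile-disaggregated household-survey coverage into a
counterfactual scale-up scenario and runs a deterministic cohort model of
deaths averted, for policy analysts and epidemiologists studying the mortality
cost of within-country inequality.

## The model

For each intervention *i* with top-quintile coverage *q₅* and national
coverage *c*, the **inequality ratio** is *r = q₅ / c*; the *applied* ratio is
max(*r*, 1) so a scale-up never lowers anyone's coverage (raw ratios are kept
unfloored in outputs — pro-poor interventions such as bednets can have
*r* < 1). The scenario raises each intervention from baseline *c₀ = c* to
target *c₁* = min(*c₀* · max(*r*, 1), 1). Interventions not measured in
surveys inherit the ratio of a co-delivered measured intervention (proxy), a
designated backup, or the contact point that delivers them (antenatal care,
facility delivery).

Baseline cause-specific deaths are *D₀* = births · rate/1000 · cause fraction.
Each intervention removes a fraction *E·AF·C* of a cause's deaths
(effectiveness × affected fraction × coverage); interventions combine
multiplicatively, leaving the residual

&nbsp;&nbsp;&nbsp;&nbsp;*R*(c) = ∏ᵢ (1 − Eᵢ·AFᵢ·cᵢ),

and scenario deaths are *D₁ = D₀ · (births₁/births₀) · R(c₁)/R(c₀)*, where
births shrink by (1 − u₁e)/(1 − u₀e) when contraceptive prevalence *u* is
scaled up (only in countries with fertility above replacement, 2.33 children
per woman). **Lives saved** = *D₀ − D₁*, attributed per intervention without
double-counting via proportional log-impact weights (order-independent, sums
exactly to the total).

The shipped catalog has 41 entries — 38 scale-up items plus 3 coverage-only
contact points — with the proxy/backup structure of co-delivered MNCH
packages. Its effectiveness and affected-fraction values are plausible
package defaults, not authoritative estimates; override them with
`--catalog your_catalog.yaml`.

## Worked example

A miniature country (100 000 births/year, NMR 30, post-neonatal rate 40) with
three effect-carrying interventions:

```python
from equilist import (make_worked_example, resolve_ratios,
                      build_scenario, run_impact)

profile, coverage, catalog = make_worked_example()
for iid, r in resolve_ratios(coverage, catalog).items():
    print(iid, r.raw_ratio, "->", r.applied_ratio)
scenario = build_scenario(profile, coverage, catalog, mode="full")
result = run_impact(profile, scenario, catalog)
print(result.lives_saved_total, result.lives_saved_by_intervention)
```

prints (abridged):

```
ors                        1.25               -> 1.25
improved_water_source      0.9166666666666667 -> 1.0
clean_postnatal_practices  1.3                -> 1.3
lives saved: 253.18885448916444
by intervention: {'cpr': 0.0, 'ors': 157.89, 'improved_water_source': 0.0,
                  'clean_postnatal_practices': 95.29}
```

ORS rises 0.40 → 0.50 and saves 2000·[1 − 0.70·0.88/(0.76·0.88)] = 157.9 of
the 2000 baseline diarrhea deaths; clean postnatal care rises 0.50 → 0.65 and
saves 1800·[1 − 0.805/0.85] = 95.3 of the 1800 neonatal sepsis deaths. The
water intervention is pro-poor (raw ratio 0.92), floors to 1, and saves
nothing; contraception is gated off because fertility (2.0) is below
replacement. Under-five mortality falls by 2.53 per 1000 live births.

## Command line

```bash
equilist simulate --n 10 --seed 42 -o data/          # synthetic survey data
equilist run --countries data/countries.csv --coverage data/coverage.csv \
             --mode full -o out/                     # multi-country analysis
equilist rank --countries data/countries.csv --coverage data/coverage.csv \
              --country SYN001                       # solo scale-up ranking
equilist ratios --countries data/countries.csv --coverage data/coverage.csv \
              -o ratios.csv                          # ratio table only
```

`run` writes `ratios.csv`, `impact.csv`, `aggregate.json`, and
`per_country.csv`; `--mode limited` restricts scale-up to survey-measured
interventions and their linked components (a conservative lower bound, since
proxied interventions stay at baseline).

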