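"""Deterministic cohort impact model: coverage change → deaths averted.

The model follows the classic lives-saved accounting for child-health
interventions.  Baseline cause-specific deaths are

    D0(band, cause) = births × rate(band)/1000 × cause_fraction(band, cause)

and already embody baseline coverage.  Each intervention *i* affecting a
cause-cell removes a fraction E_i·AF_i·C_i of that cause's deaths, where E is
effectiveness, AF the affected fraction, and C coverage; interventions combine
multiplicatively, so the surviving ("residual") share of deaths at coverage
vector c is

    R(c) = Π_i (1 − E_i·AF_i·c_i).

Because D0 is measured under baseline coverage c0, the scenario deaths are
normalized to baseline:

    D1 = D0 × (births1/births0) × R(c1)/R(c0),

with births1 ≤ births0 when contraceptive scale-up shrinks the birth cohort:
births1 = births0 × (1 − u1·e)/(1 − u0·e), u = contraceptive prevalence and
e its use-effectiveness.

Lives saved are attributed per intervention without double-counting: the
fertility component of each cell goes to contraception, and the remaining cell
savings are split proportionally to each intervention's solo log-impact
w_i = ln[(1 − E_i·AF_i·c0_i) / (1 − E_i·AF_i·c1_i)], an order-independent rule
whose shares sum exactly to the cell total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

from .country_data import (
    AGE_BANDS,
    DIRECT,
    LINKED,
    NEONATAL,
    POSTNEONATAL,
    CountryProfile,
    InterventionCatalog,
)
from .errors import ModelError
from .inequality import Scenario

logger = logging.getLogger(__name__)

_DEGENERATE_TOL = 1e-12


@dataclass
class ImpactResult:
    """Deaths, lives saved and rate changes for one country under one scenario.

    Deaths are indexed by ``(age_band, cause)``; rate changes are scenario
    minus baseline, per 1000 live births (negative = mortality decline).
    """

    country_id: str
    mode: str
    deaths_baseline: dict  # (age_band, cause) -> deaths
    deaths_scenario: dict
    births_baseline: float
    births_scenario: float
    lives_saved_total: float
    lives_saved_by_intervention: dict
    lives_saved_by_age: dict
    u5mr_change: float
    nmr_change: float

    def deaths_by_age(self, which: str = "baseline") -> dict:
        src = self.deaths_baseline if which == "baseline" else self.deaths_scenario
        out = {band: 0.0 for band in AGE_BANDS}
        for (band, _), d in src.items():
            out[band] += d
        return out


def effective_coverage(scenario: Scenario, catalog: InterventionCatalog) -> dict:
    """(baseline, target) coverage pair per intervention.

    Directly measured and proxied interventions use their own scenario entries;
    linked components inherit their parent contact point's pair.  An
    intervention absent from the scenario contributes nothing: pair (0, 0).
    """
    out = {}
    for iid, spec in catalog.interventions.items():
        key = spec.channel.parent_id if spec.channel.kind == LINKED else iid
        if key in scenario.baseline_coverage:
            out[iid] = (scenario.baseline_coverage[key], scenario.target_coverage[key])
        else:
            if spec.channel.kind == LINKED:
                logger.warning(
                    "%s: linked parent %s absent from scenario; %s kept at (0, 0)",
                    scenario.country_id, key, iid,
                )
            out[iid] = (0.0, 0.0)
    return out


def births_under_scenario(
    profile: CountryProfile,
    scenario: Scenario,
    catalog: InterventionCatalog,
) -> float:
    """Birth cohort size under the scenario.

    When contraceptive prevalence is scaled from u0 to u1 with use-effectiveness
    e, births scale by (1 − u1·e)/(1 − u0·e); otherwise they are unchanged.
    """
    if not scenario.cpr_scaled:
        return profile.live_births
    cov = effective_coverage(scenario, catalog)
    u0, u1 = cov[catalog.cpr_id]
    e = catalog.cpr_effectiveness
    if u1 * e >= 1.0 - _DEGENERATE_TOL:
        raise ModelError(
            f"contraceptive prevalence {u1} at effectiveness {e} removes all "
            "fecund exposure"
        )
    births = profile.live_births * (1.0 - u1 * e) / (1.0 - u0 * e)
    return min(max(births, _DEGENERATE_TOL), profile.live_births)


def residual_fraction(
    cause: str,
    age_band: str,
    coverages: Mapping[str, float],
    catalog: InterventionCatalog,
) -> float:
    """Surviving share of (cause, age_band) deaths at the given coverages:
    Π (1 − E·AF·C) over affecting interventions; empty product = 1."""
    r = 1.0
    for iid, eff in catalog.effects_on(cause, age_band):
        c = coverages.get(iid, 0.0)
        term = 1.0 - eff.impact * c
        if term < _DEGENERATE_TOL:
            raise ModelError(
                f"{iid} on ({age_band}, {cause}): effectiveness × affected "
                f"fraction × coverage = {eff.impact * c} leaves no residual"
            )
        r *= term
    return r


def _band_rate(profile: CountryProfile, band: str) -> float:
    return profile.nmr if band == NEONATAL else profile.post_nmr


def run_impact(
    profile: CountryProfile,
    scenario: Scenario,
    catalog: InterventionCatalog,
) -> ImpactResult:
    """Run the cohort model for one country and scenario."""
    cov = effective_coverage(scenario, catalog)
    c0 = {i: p[0] for i, p in cov.items()}
    c1 = {i: p[1] for i, p in cov.items()}
    births0 = profile.live_births
    births1 = births_under_scenario(profile, scenario, catalog)
    birth_ratio = births1 / births0
    cpr_id = catalog.cpr_id

    fractions = {
        NEONATAL: profile.neonatal_cause_fractions,
        POSTNEONATAL: profile.postneonatal_cause_fractions,
    }

    deaths0: dict = {}
    deaths1: dict = {}
    attribution: dict = {iid: 0.0 for iid in catalog.interventions}

    for band in AGE_BANDS:
        rate = _band_rate(profile, band)
        for cause in catalog.causes(band):
            frac = fractions[band].get(cause, 0.0)
            d0 = births0 * rate / 1000.0 * frac
            r0 = residual_fraction(cause, band, c0, catalog)
            r1 = residual_fraction(cause, band, c1, catalog)
            d1 = d0 * birth_ratio * r1 / r0
            deaths0[(band, cause)] = d0
            deaths1[(band, cause)] = d1

            # attribution: fertility share to contraception, the rest split by
            # solo log-impact weights (order-independent, sums to cell total)
            attribution[cpr_id] += d0 * (1.0 - birth_ratio)
            cell_rest = d0 * birth_ratio * (1.0 - r1 / r0)
            if cell_rest > 0.0:
                weights = {}
                for iid, eff in catalog.effects_on(cause, band):
                    t0 = 1.0 - eff.impact * c0[iid]
                    t1 = 1.0 - eff.impact * c1[iid]
                    w = math.log(t0 / t1)
                    if w > 0.0:
                        weights[iid] = w
                total_w = sum(weights.values())
                if total_w > 0.0:
                    for iid, w in weights.items():
                        attribution[iid] += cell_rest * w / total_w

    total0 = sum(deaths0.values())
    total1 = sum(deaths1.values())
    by_age_saved = {}
    by_age0 = {band: 0.0 for band in AGE_BANDS}
    by_age1 = {band: 0.0 for band in AGE_BANDS}
    for (band, _), d in deaths0.items():
        by_age0[band] += d
    for (band, _), d in deaths1.items():
        by_age1[band] += d
    for band in AGE_BANDS:
        by_age_saved[band] = by_age0[band] - by_age1[band]

    nmr0 = 1000.0 * by_age0[NEONATAL] / births0
    nmr1 = 1000.0 * by_age1[NEONATAL] / births1
    u5mr0 = 1000.0 * total0 / births0
    u5mr1 = 1000.0 * total1 / births1

    return ImpactResult(
        country_id=profile.country_id,
        mode=scenario.mode,
        deaths_baseline=deaths0,
        deaths_scenario=deaths1,
        births_baseline=births0,
        births_scenario=births1,
        lives_saved_total=total0 - total1,
        lives_saved_by_intervention=attribution,
        lives_saved_by_age=by_age_saved,
        u5mr_change=u5mr1 - u5mr0,
        nmr_change=nmr1 - nmr0,
    )
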