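"""Shared fixtures: worked example, default catalog, random model instances."""

import numpy as np
import pytest

from equilist import (
    CountryProfile,
    CoverageEntry,
    CoverageTable,
    Scenario,
    catalog_from_dict,
    default_catalog,
    make_worked_example,
)

NEO_CAUSES = ["sepsis_pneumonia", "other_neonatal"]
POST_CAUSES = ["diarrhea", "other_postneonatal"]


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def worked_example():
    return make_worked_example()


def make_mini_catalog(effect_rows, cpr_effectiveness=0.9, fertility_gate=2.33):
    """Catalog of direct interventions from (id, cause, band, E, AF) rows plus a CPR."""
    by_id = {}
    for iid, cause, band, e, af in effect_rows:
        by_id.setdefault(iid, []).append(
            {"cause": cause, "age_band": band, "effectiveness": e, "affected_fraction": af}
        )
    interventions = [{"id": "cpr", "channel": "direct", "is_cpr": True, "effects": []}]
    interventions += [
        {"id": iid, "channel": "direct", "effects": effects}
        for iid, effects in by_id.items()
    ]
    return catalog_from_dict({
        "cpr_effectiveness": cpr_effectiveness,
        "fertility_gate": fertility_gate,
        "neonatal_causes": NEO_CAUSES,
        "postneonatal_causes": POST_CAUSES,
        "interventions": interventions,
    })


def make_profile(country_id="TST", births=500_000, nmr=25.0, post_nmr=35.0,
                 tfr=2.0, neo_frac=0.6, post_frac=0.5, survey_year=2012):
    return CountryProfile(
        country_id=country_id,
        live_births=births,
        nmr=nmr,
        post_nmr=post_nmr,
        tfr=tfr,
        survey_year=survey_year,
        neonatal_cause_fractions={"sepsis_pneumonia": neo_frac,
                                  "other_neonatal": 1 - neo_frac},
        postneonatal_cause_fractions={"diarrhea": post_frac,
                                      "other_postneonatal": 1 - post_frac},
    )


def make_scenario(baseline, target, country_id="TST", mode="full", cpr_scaled=False):
    return Scenario(
        country_id=country_id, mode=mode,
        baseline_coverage=baseline, target_coverage=target,
        cpr_scaled=cpr_scaled,
    )


def random_instance(rng: np.random.Generator, max_interventions=3, cpr_scaled=False):
    """A random small model instance: (profile, catalog, scenario).

    Up to ``max_interventions`` effect-carrying interventions acting on up to
    two causes (one per age band), plus a CPR whose coverage moves only when
    ``cpr_scaled``.
    """
    n_int = int(rng.integers(1, max_interventions + 1))
    causes = [("sepsis_pneumonia", "neonatal"), ("diarrhea", "postneonatal")]
    rows = []
    for k in range(n_int):
        iid = f"i{k}"
        for cause, band in causes:
            if rng.uniform() < 0.7:
                rows.append((iid, cause, band,
                             float(rng.uniform(0.05, 0.9)),
                             float(rng.uniform(0.1, 1.0))))
    if not rows:  # guarantee at least one effect
        rows.append(("i0", "diarrhea", "postneonatal", 0.5, 0.8))
    cat = make_mini_catalog(rows)
    profile = make_profile(
        births=float(rng.uniform(1e5, 2e6)),
        nmr=float(rng.uniform(10, 45)),
        post_nmr=float(rng.uniform(10, 70)),
        tfr=float(rng.uniform(3.0, 6.0)) if cpr_scaled else 2.0,
        neo_frac=float(rng.uniform(0.2, 0.8)),
        post_frac=float(rng.uniform(0.2, 0.8)),
    )
    baseline, target = {}, {}
    for iid in cat.interventions:
        if iid == "cpr":
            u0 = float(rng.uniform(0.05, 0.5))
            baseline[iid] = u0
            target[iid] = min(u0 * float(rng.uniform(1.0, 1.5)), 1.0) if cpr_scaled else u0
        else:
            c0 = float(rng.uniform(0.0, 0.9))
            baseline[iid] = c0
            target[iid] = min(c0 * float(rng.uniform(1.0, 1.6)), 1.0)
    scenario = make_scenario(baseline, target, cpr_scaled=cpr_scaled)
    return profile, cat, scenario


def oracle_impact(profile, catalog, scenario):
    """Direct evaluation of the model formulas, independent of the engine.

    Loops explicitly over cells and interventions: D0 from rates and cause
    fractions, residuals as raw products, births via the contraception
    formula.  Returns (deaths0, deaths1) keyed by (band, cause).
    """
    b0 = profile.live_births
    if scenario.cpr_scaled:
        e = catalog.cpr_effectiveness
        u0 = scenario.baseline_coverage["cpr"]
        u1 = scenario.target_coverage["cpr"]
        b1 = b0 * (1 - u1 * e) / (1 - u0 * e)
    else:
        b1 = b0
    fractions = {"neonatal": profile.neonatal_cause_fractions,
                 "postneonatal": profile.postneonatal_cause_fractions}
    rates = {"neonatal": profile.nmr, "postneonatal": profile.post_nmr}
    deaths0, deaths1 = {}, {}
    for band in ("neonatal", "postneonatal"):
        for cause in catalog.causes(band):
            d0 = b0 * rates[band] / 1000.0 * fractions[band].get(cause, 0.0)
            r0 = r1 = 1.0
            for iid, spec in catalog.interventions.items():
                for eff in spec.effects:
                    if eff.cause == cause and eff.age_band == band:
                        ea = eff.effectiveness * eff.affected_fraction
                        r0 *= 1.0 - ea * scenario.baseline_coverage.get(iid, 0.0)
                        r1 *= 1.0 - ea * scenario.target_coverage.get(iid, 0.0)
            deaths0[(band, cause)] = d0
            deaths1[(band, cause)] = d0 * (b1 / b0) * r1 / r0
    return deaths0, deaths1
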