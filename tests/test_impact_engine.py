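"""The cohort impact model against closed-form and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from equilist import (
    ModelError,
    births_under_scenario,
    effective_coverage,
    make_worked_example,
    residual_fraction,
    run_impact,
    WORKED_EXAMPLE_LIVES_SAVED,
)
from equilist.inequality import build_scenario

from conftest import (
    make_mini_catalog,
    make_profile,
    make_scenario,
    oracle_impact,
    random_instance,
)


# ---------------------------------------------------------------------------
# effective coverage
# ---------------------------------------------------------------------------


def test_linked_child_inherits_parent_coverage_pair(catalog):
    base = {"facility_delivery": 0.50}
    s = make_scenario(base, {"facility_delivery": 0.70})
    cov = effective_coverage(s, catalog)
    assert cov["neonatal_resuscitation"] == (0.50, 0.70)
    assert cov["labor_delivery_management"] == (0.50, 0.70)


def test_direct_intervention_uses_own_pair(catalog):
    s = make_scenario({"ors": 0.40}, {"ors": 0.466})
    assert effective_coverage(s, catalog)["ors"] == (0.40, 0.466)


def test_absent_parent_gives_zero_pair_with_warning(catalog, caplog):
    s = make_scenario({"ors": 0.4}, {"ors": 0.4})
    with caplog.at_level("WARNING"):
        cov = effective_coverage(s, catalog)
    assert cov["neonatal_resuscitation"] == (0.0, 0.0)
    assert any("facility_delivery" in r.message for r in caplog.records)


def test_contact_points_carry_no_effects(catalog):
    for parent in ("antenatal_care", "skilled_birth_attendant", "facility_delivery"):
        assert catalog.interventions[parent].effects == ()


# ---------------------------------------------------------------------------
# births under contraceptive scale-up
# ---------------------------------------------------------------------------


def test_births_formula_hand_value():
    cat = make_mini_catalog([("i0", "diarrhea", "postneonatal", 0.5, 0.8)])
    profile = make_profile(births=1_000_000, tfr=4.0)
    s = make_scenario({"cpr": 0.20, "i0": 0.4}, {"cpr": 0.30, "i0": 0.4},
                      cpr_scaled=True)
    births = births_under_scenario(profile, s, cat)
    # 1_000_000 * (1 - 0.27) / (1 - 0.18)
    assert births == pytest.approx(1_000_000 * 0.73 / 0.82)
    assert births == pytest.approx(890_243.9, abs=0.05)


def test_births_unchanged_without_cpr_scaleup():
    cat = make_mini_catalog([("i0", "diarrhea", "postneonatal", 0.5, 0.8)])
    profile = make_profile(births=1_000_000)
    s = make_scenario({"cpr": 0.20, "i0": 0.4}, {"cpr": 0.20, "i0": 0.5})
    assert births_under_scenario(profile, s, cat) == 1_000_000


def test_births_unchanged_when_cpr_pair_equal():
    cat = make_mini_catalog([("i0", "diarrhea", "postneonatal", 0.5, 0.8)])
    profile = make_profile(births=1_000_000, tfr=4.0)
    s = make_scenario({"cpr": 0.25, "i0": 0.4}, {"cpr": 0.25, "i0": 0.4},
                      cpr_scaled=True)
    assert births_under_scenario(profile, s, cat) == pytest.approx(1_000_000)


def test_degenerate_contraception_raises():
    cat = make_mini_catalog([("i0", "diarrhea", "postneonatal", 0.5, 0.8)],
                            cpr_effectiveness=1.0)
    profile = make_profile(tfr=4.0)
    s = make_scenario({"cpr": 0.5, "i0": 0.4}, {"cpr": 1.0, "i0": 0.4},
                      cpr_scaled=True)
    with pytest.raises(ModelError):
        births_under_scenario(profile, s, cat)


# ---------------------------------------------------------------------------
# residual fraction
# ---------------------------------------------------------------------------


def test_residual_empty_product_is_one():
    cat = make_mini_catalog([("i0", "diarrhea", "postneonatal", 0.5, 1.0)])
    assert residual_fraction("sepsis_pneumonia", "neonatal", {"i0": 0.4}, cat) == 1.0


def test_residual_single_intervention():
    cat = make_mini_catalog([("i0", "diarrhea", "postneonatal", 0.5, 1.0)])
    assert residual_fraction("diarrhea", "postneonatal", {"i0": 0.4}, cat) \
        == pytest.approx(0.8)


def test_residual_two_interventions_multiply():
    cat = make_mini_catalog([
        ("i0", "diarrhea", "postneonatal", 0.5, 1.0),   # E*AF*C = 0.2 at C=0.4
        ("i1", "diarrhea", "postneonatal", 0.25, 1.0),  # E*AF*C = 0.1 at C=0.4
    ])
    got = residual_fraction("diarrhea", "postneonatal", {"i0": 0.4, "i1": 0.4}, cat)
    assert got == pytest.approx(0.8 * 0.9)


# ---------------------------------------------------------------------------
# run_impact: closed form, brute force, conservation
# ---------------------------------------------------------------------------


def test_null_scenario_saves_nothing():
    cat = make_mini_catalog([("i0", "diarrhea", "postneonatal", 0.5, 0.8)])
    profile = make_profile()
    s = make_scenario({"cpr": 0.2, "i0": 0.4}, {"cpr": 0.2, "i0": 0.4})
    r = run_impact(profile, s, cat)
    assert r.lives_saved_total == pytest.approx(0.0, abs=1e-12)
    assert r.u5mr_change == pytest.approx(0.0, abs=1e-12)
    assert r.nmr_change == pytest.approx(0.0, abs=1e-12)


def test_single_intervention_closed_form_hand_value():
    # D0=10000, E=0.6, AF=1, c0=0.2, c1=0.7 -> D1 = 10000*(1-0.42)/(1-0.12)
    cat = make_mini_catalog([("i0", "diarrhea", "postneonatal", 0.6, 1.0)])
    profile = make_profile(births=500_000, post_nmr=40.0, post_frac=0.5, nmr=0.0)
    assert profile.live_births * profile.post_nmr / 1000 * 0.5 == 10_000
    s = make_scenario({"cpr": 0.2, "i0": 0.2}, {"cpr": 0.2, "i0": 0.7})
    r = run_impact(profile, s, cat)
    d1 = r.deaths_scenario[("postneonatal", "diarrhea")]
    assert d1 == pytest.approx(10_000 * 0.58 / 0.88, abs=1e-6)
    assert r.lives_saved_total == pytest.approx(10_000 - 10_000 * 0.58 / 0.88, abs=1e-6)
    assert r.lives_saved_by_intervention["i0"] == pytest.approx(r.lives_saved_total)


@pytest.mark.parametrize("e", [0.1, 0.5, 0.9])
@pytest.mark.parametrize("af", [0.25, 1.0])
@pytest.mark.parametrize("c0,c1", [(0.0, 0.5), (0.2, 0.7), (0.5, 0.5), (0.8, 1.0)])
def test_single_intervention_averted_fraction_closed_form(e, af, c0, c1):
    """Fraction of cause deaths averted = [(1-E*AF*c0)-(1-E*AF*c1)]/(1-E*AF*c0)."""
    cat = make_mini_catalog([("i0", "diarrhea", "postneonatal", e, af)])
    profile = make_profile()
    s = make_scenario({"cpr": 0.2, "i0": c0}, {"cpr": 0.2, "i0": c1})
    r = run_impact(profile, s, cat)
    d0 = r.deaths_baseline[("postneonatal", "diarrhea")]
    d1 = r.deaths_scenario[("postneonatal", "diarrhea")]
    expected = ((1 - e * af * c0) - (1 - e * af * c1)) / (1 - e * af * c0)
    assert (d0 - d1) / d0 == pytest.approx(expected, abs=1e-9)


def test_brute_force_oracle_and_conservation():
    """1000 random instances (≤3 interventions × ≤2 causes): the engine matches
    direct evaluation of the product formula, and attribution conserves."""
    rng = np.random.default_rng(20160925)
    for trial in range(1000):
        cpr_scaled = bool(rng.uniform() < 0.3)
        profile, cat, s = random_instance(rng, cpr_scaled=cpr_scaled)
        r = run_impact(profile, s, cat)
        exp0, exp1 = oracle_impact(profile, cat, s)
        for key in exp0:
            assert r.deaths_baseline[key] == pytest.approx(exp0[key], abs=1e-9, rel=1e-9)
            assert r.deaths_scenario[key] == pytest.approx(exp1[key], abs=1e-9, rel=1e-9)
        total = sum(r.lives_saved_by_intervention.values())
        assert total == pytest.approx(r.lives_saved_total, rel=1e-6, abs=1e-9)


def test_order_independence():
    """Permuting the intervention catalog order changes nothing."""
    rng = np.random.default_rng(11)
    for trial in range(200):
        profile, cat, s = random_instance(rng)
        r = run_impact(profile, s, cat)
        ids = list(cat.interventions)
        perm = [ids[i] for i in rng.permutation(len(ids))]
        cat_perm = type(cat)(
            interventions={i: cat.interventions[i] for i in perm},
            cpr_effectiveness=cat.cpr_effectiveness,
            fertility_gate=cat.fertility_gate,
            neonatal_causes=cat.neonatal_causes,
            postneonatal_causes=cat.postneonatal_causes,
        )
        r2 = run_impact(profile, s, cat_perm)
        assert r2.lives_saved_total == pytest.approx(r.lives_saved_total, rel=1e-12)
        for iid in cat.interventions:
            assert r2.lives_saved_by_intervention[iid] == pytest.approx(
                r.lives_saved_by_intervention[iid], rel=1e-9, abs=1e-12)


def test_monotonicity_in_target_coverage():
    """Raising any single target coverage never decreases lives saved."""
    rng = np.random.default_rng(12)
    for trial in range(200):
        profile, cat, s = random_instance(rng)
        base_saved = run_impact(profile, s, cat).lives_saved_total
        iid = str(rng.choice([i for i in cat.interventions if i != "cpr"]))
        bumped = dict(s.target_coverage)
        bumped[iid] = min(bumped[iid] + float(rng.uniform(0.0, 0.3)), 1.0)
        s2 = make_scenario(dict(s.baseline_coverage), bumped,
                           cpr_scaled=s.cpr_scaled)
        assert run_impact(profile, s2, cat).lives_saved_total >= base_saved - 1e-9


def test_zero_effect_interventions_get_no_attribution():
    cat = make_mini_catalog([
        ("i0", "diarrhea", "postneonatal", 0.5, 0.8),
        ("dud", "diarrhea", "postneonatal", 0.0, 1.0),
    ])
    profile = make_profile()
    s = make_scenario({"cpr": 0.2, "i0": 0.3, "dud": 0.3},
                      {"cpr": 0.2, "i0": 0.6, "dud": 0.9})
    r = run_impact(profile, s, cat)
    assert r.lives_saved_by_intervention["dud"] == 0.0
    assert r.lives_saved_by_intervention["cpr"] == 0.0  # not scaled


def test_u5_accounting_is_band_sum():
    rng = np.random.default_rng(13)
    for trial in range(50):
        profile, cat, s = random_instance(rng, cpr_scaled=True)
        r = run_impact(profile, s, cat)
        assert r.lives_saved_total == pytest.approx(
            r.lives_saved_by_age["neonatal"] + r.lives_saved_by_age["postneonatal"],
            rel=1e-12, abs=1e-9)
        assert all(d1 <= d0 + 1e-12 for (k, d0), d1 in
                   zip(r.deaths_baseline.items(),
                       (r.deaths_scenario[k] for k in r.deaths_baseline)))


def test_fertility_savings_attributed_to_contraception():
    cat = make_mini_catalog([("i0", "diarrhea", "postneonatal", 0.5, 0.8)])
    profile = make_profile(births=1_000_000, tfr=4.0)
    s = make_scenario({"cpr": 0.20, "i0": 0.4}, {"cpr": 0.30, "i0": 0.4},
                      cpr_scaled=True)
    r = run_impact(profile, s, cat)
    birth_ratio = (1 - 0.27) / (1 - 0.18)
    expected = sum(r.deaths_baseline.values()) * (1 - birth_ratio)
    assert r.lives_saved_by_intervention["cpr"] == pytest.approx(expected, rel=1e-12)
    assert r.lives_saved_by_intervention["i0"] == pytest.approx(0.0, abs=1e-12)
    assert r.births_scenario == pytest.approx(1_000_000 * birth_ratio)


def test_worked_example_reproduces_hand_derivation(worked_example):
    profile, coverage, cat = worked_example
    s = build_scenario(profile, coverage, cat, mode="full")
    r = run_impact(profile, s, cat)
    assert r.lives_saved_total == pytest.approx(WORKED_EXAMPLE_LIVES_SAVED, abs=1e-9)
    assert r.lives_saved_by_intervention["ors"] == pytest.approx(6000 / 38, abs=1e-9)
    assert r.lives_saved_by_intervention["clean_postnatal_practices"] == \
        pytest.approx(16200 / 170, abs=1e-9)
    # the pro-poor water intervention floors to ratio 1: no savings attributed
    assert r.lives_saved_by_intervention["improved_water_source"] == 0.0
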