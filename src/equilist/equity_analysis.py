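"""Multi-country equity analysis: scale every country to top-quintile coverage.

Runs the full or limited scale-up scenario for each country, sums deaths and
lives saved across countries, and reports the percent of deaths averted per
age band — the aggregate counterfactual of eliminating within-country wealth
inequality in intervention coverage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .country_data import AGE_BANDS, CountryProfile, CoverageTable, InterventionCatalog
from .impact_engine import ImpactResult, run_impact
from .inequality import FULL, LIMITED, Scenario, build_scenario

logger = logging.getLogger(__name__)


@dataclass
class AggregateResult:
    """Aggregated deaths and lives saved across countries for one mode."""

    mode: str
    n_countries: int
    deaths_baseline_by_age: dict
    deaths_scenario_by_age: dict
    pct_averted_by_age: dict
    pct_averted_u5: float
    lives_saved_by_intervention: dict
    per_country: list  # of dicts: country_id, u5mr_change, nmr_change, lives_saved
    skipped: list = field(default_factory=list)

    @property
    def lives_saved_total(self) -> float:
        return sum(r["lives_saved"] for r in self.per_country)

    @property
    def deaths_baseline_u5(self) -> float:
        return sum(self.deaths_baseline_by_age.values())

    @property
    def deaths_scenario_u5(self) -> float:
        return sum(self.deaths_scenario_by_age.values())

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_countries": self.n_countries,
            "deaths_baseline_by_age": self.deaths_baseline_by_age,
            "deaths_scenario_by_age": self.deaths_scenario_by_age,
            "deaths_baseline_u5": self.deaths_baseline_u5,
            "deaths_scenario_u5": self.deaths_scenario_u5,
            "pct_averted_by_age": self.pct_averted_by_age,
            "pct_averted_u5": self.pct_averted_u5,
            "lives_saved_total": self.lives_saved_total,
            "lives_saved_by_intervention": self.lives_saved_by_intervention,
            "skipped": self.skipped,
        }


def _pct(baseline: float, scenario: float) -> float:
    if baseline <= 0.0:
        return 0.0
    return 100.0 * (baseline - scenario) / baseline


def run_equity_analysis(
    profiles: Sequence[CountryProfile],
    coverages: Mapping[str, CoverageTable],
    catalog: InterventionCatalog,
    mode: str = FULL,
    min_survey_year: Optional[int] = None,
) -> AggregateResult:
    """Build and run the mode's scenario for each country and aggregate.

    Countries lacking a coverage table (or surveyed before ``min_survey_year``)
    are skipped with a warning and listed in the result's ``skipped`` report.
    """
    deaths0 = {band: 0.0 for band in AGE_BANDS}
    deaths1 = {band: 0.0 for band in AGE_BANDS}
    by_intervention: dict = {iid: 0.0 for iid in catalog.interventions}
    per_country = []
    skipped = []

    for profile in profiles:
        if min_survey_year is not None and profile.survey_year < min_survey_year:
            skipped.append({"country_id": profile.country_id,
                            "reason": f"survey_year {profile.survey_year} < {min_survey_year}"})
            continue
        coverage = coverages.get(profile.country_id)
        if coverage is None:
            logger.warning("%s: no coverage table; country skipped", profile.country_id)
            skipped.append({"country_id": profile.country_id, "reason": "no coverage table"})
            continue
        scenario = build_scenario(profile, coverage, catalog, mode=mode)
        result = run_impact(profile, scenario, catalog)
        b0 = result.deaths_by_age("baseline")
        b1 = result.deaths_by_age("scenario")
        for band in AGE_BANDS:
            deaths0[band] += b0[band]
            deaths1[band] += b1[band]
        for iid, saved in result.lives_saved_by_intervention.items():
            by_intervention[iid] = by_intervention.get(iid, 0.0) + saved
        per_country.append({
            "country_id": profile.country_id,
            "u5mr_change": result.u5mr_change,
            "nmr_change": result.nmr_change,
            "lives_saved": result.lives_saved_total,
        })

    pct_by_age = {band: _pct(deaths0[band], deaths1[band]) for band in AGE_BANDS}
    return AggregateResult(
        mode=mode,
        n_countries=len(per_country),
        deaths_baseline_by_age=deaths0,
        deaths_scenario_by_age=deaths1,
        pct_averted_by_age=pct_by_age,
        pct_averted_u5=_pct(sum(deaths0.values()), sum(deaths1.values())),
        lives_saved_by_intervention=by_intervention,
        per_country=per_country,
        skipped=skipped,
    )


def intervention_league_table(result: AggregateResult, top_k: Optional[int] = None) -> list:
    """Interventions ordered by lives saved (descending, ties broken by id)."""
    rows = sorted(
        result.lives_saved_by_intervention.items(),
        key=lambda kv: (-kv[1], kv[0]),
    )
    if top_k is not None:
        rows = rows[: max(top_k, 0)]
    return rows


def write_aggregate(result: AggregateResult, path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(result.to_dict(), fh, indent=1)


def write_per_country(result: AggregateResult, path) -> None:
    pd.DataFrame(
        result.per_country, columns=["country_id", "u5mr_change", "nmr_change", "lives_saved"]
    ).to_csv(Path(path), index=False)
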