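"""Single-intervention ranking for one country (the "equity tool" view).

Each intervention with a usable inequality ratio is scaled up alone from the
national average to the top-wealth-quintile level, the cohort model is run,
and interventions are ranked by the number of lives saved.  Contact points
(antenatal care, facility delivery) are ranked as bundles that move their
linked components.  Because each row is a solo scale-up, the rows ignore
cross-intervention interactions and their sum need not match a joint run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .country_data import (
    LINKED,
    NEONATAL,
    POSTNEONATAL,
    CountryProfile,
    CoverageTable,
    InterventionCatalog,
)
from .impact_engine import run_impact
from .inequality import SINGLE, build_scenario, resolve_ratios

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankingFilters:
    """Optional restrictions on the ranking view.

    ``age_band`` picks the sort column (``neonatal``, ``child`` for
    post-neonatal, or total); ``groups`` and ``causes`` restrict which
    interventions appear.  Filters never change a row's values, only
    membership and ordering.
    """

    age_band: Optional[str] = None  # neonatal | child | None (total)
    groups: Optional[frozenset] = None
    causes: Optional[frozenset] = None


@dataclass(frozen=True)
class RankingRow:
    intervention_id: str
    lives_saved_neonatal: float
    lives_saved_child: float

    @property
    def lives_saved_total(self) -> float:
        return self.lives_saved_neonatal + self.lives_saved_child


@dataclass
class EquityRanking:
    country_id: str
    rows: list  # of RankingRow, sorted for the active filters
    filters: RankingFilters = field(default_factory=RankingFilters)
    status: str = "ok"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "intervention_id": r.intervention_id,
                    "lives_saved_neonatal": r.lives_saved_neonatal,
                    "lives_saved_child": r.lives_saved_child,
                    "lives_saved_total": r.lives_saved_total,
                }
                for r in self.rows
            ],
            columns=[
                "intervention_id", "lives_saved_neonatal",
                "lives_saved_child", "lives_saved_total",
            ],
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(Path(path), index=False)


def _sort_key(filters: RankingFilters):
    if filters.age_band == NEONATAL:
        return lambda r: (-r.lives_saved_neonatal, r.intervention_id)
    if filters.age_band in ("child", POSTNEONATAL):
        return lambda r: (-r.lives_saved_child, r.intervention_id)
    return lambda r: (-r.lives_saved_total, r.intervention_id)


def _bundle_causes(catalog: InterventionCatalog, iid: str) -> set:
    specs = [catalog.interventions[iid]]
    specs += [catalog.interventions[c] for c in catalog.linked_children(iid)]
    return {eff.cause for s in specs for eff in s.effects}


def _bundle_groups(catalog: InterventionCatalog, iid: str) -> set:
    groups = {catalog.interventions[iid].group}
    groups |= {catalog.interventions[c].group for c in catalog.linked_children(iid)}
    return groups


def rank_interventions(
    profile: CountryProfile,
    coverage: CoverageTable,
    catalog: InterventionCatalog,
    filters: Optional[RankingFilters] = None,
) -> EquityRanking:
    """Rank interventions by lives saved when each is scaled up alone.

    Rankable items are every non-linked catalog intervention with an available
    inequality ratio and a national baseline; linked components are covered by
    their parent's bundle row.  Rows with zero lives saved are retained at the
    bottom of the ranking.
    """
    filters = filters or RankingFilters()
    ratios = resolve_ratios(coverage, catalog)

    rows = []
    for iid, spec in catalog.interventions.items():
        if spec.channel.kind == LINKED:
            continue  # ranked inside the parent bundle
        r = ratios[iid]
        if not r.available:
            continue
        entry = coverage.entries.get(iid)
        if entry is None or entry.national is None:
            continue
        scenario = build_scenario(
            profile, coverage, catalog, mode=SINGLE, single_id=iid, ratios=ratios
        )
        impact = run_impact(profile, scenario, catalog)
        rows.append(RankingRow(
            intervention_id=iid,
            lives_saved_neonatal=impact.lives_saved_by_age[NEONATAL],
            lives_saved_child=impact.lives_saved_by_age[POSTNEONATAL],
        ))

    if not rows:
        return EquityRanking(
            country_id=profile.country_id, rows=[], filters=filters,
            status="no inequality ratios available for this survey",
        )

    if filters.groups is not None:
        keep = frozenset(filters.groups)
        rows = [r for r in rows if _bundle_groups(catalog, r.intervention_id) & keep]
    if filters.causes is not None:
        keep = frozenset(filters.causes)
        rows = [r for r in rows if _bundle_causes(catalog, r.intervention_id) & keep]

    rows.sort(key=_sort_key(filters))
    return EquityRanking(country_id=profile.country_id, rows=rows, filters=filters)
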