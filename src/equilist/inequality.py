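"""Inequality ratios, proxy/backup resolution, and scale-up scenarios.

The inequality ratio of an intervention is its top-wealth-quintile coverage
divided by its national coverage; a ratio above one means the richest fifth of
the population is better covered than the country as a whole.  Raw ratios are
reported unfloored (pro-poor interventions such as bednets can have ratios
below one), while *applied* ratios are floored at one so that a scale-up
scenario never reduces anyone's coverage.

Interventions without survey data inherit the ratio of a co-delivered measured
intervention (proxy), or of a designated backup when the survey lacks the
primary indicator.  Backup resolution is one level deep: a direct intervention
falls back to its named backup's own ratio, never to the backup's backup.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .country_data import (
    DIRECT,
    LINKED,
    PROXIED,
    CountryProfile,
    CoverageEntry,
    CoverageTable,
    InterventionCatalog,
)

logger = logging.getLogger(__name__)

FULL = "full"
LIMITED = "limited"
SINGLE = "single"

#: Provenance kinds for a resolved ratio.
PROV_DIRECT = "direct"
PROV_PROXY = "proxy"
PROV_BACKUP = "backup"
PROV_UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class InequalityRatio:
    """A resolved inequality ratio for one intervention.

    ``raw_ratio`` is the unfloored top-quintile / national quotient taken from
    the provenance source; ``applied_ratio`` is max(raw, 1).  ``provenance``
    records where the ratio came from: ``direct``, ``proxy``/``backup`` with a
    ``source_id``, or ``unavailable``.
    """

    intervention_id: str
    raw_ratio: Optional[float]
    applied_ratio: Optional[float]
    provenance: str
    source_id: Optional[str] = None

    def __post_init__(self):
        if self.provenance == PROV_UNAVAILABLE:
            assert self.applied_ratio is None
        else:
            assert self.applied_ratio is not None
            assert self.applied_ratio >= 1.0

    @property
    def available(self) -> bool:
        return self.provenance != PROV_UNAVAILABLE


def compute_raw_ratio(entry: Optional[CoverageEntry]) -> Optional[float]:
    """Top-quintile coverage divided by national coverage, unfloored.

    Returns ``None`` when either value is missing or national coverage is zero
    (an undefined ratio, logged rather than raised).
    """
    if entry is None:
        return None
    q5 = entry.top_quintile
    if q5 is None or entry.national is None:
        return None
    if entry.national == 0.0:
        if q5 > 0:
            logger.info("national coverage 0 with top quintile %.3f: ratio undefined", q5)
        return None
    return q5 / entry.national


def resolve_ratios(coverage: CoverageTable, catalog: InterventionCatalog) -> dict:
    """Resolve an inequality ratio for every catalog intervention.

    Resolution order: a directly measured intervention uses its own survey
    ratio, then its backup's; a proxied intervention uses its source's resolved
    ratio, then its own backup's; a linked component takes its parent contact
    point's ratio.  Flooring at one happens after resolution, on the final
    applied value.
    """
    own = {
        iid: compute_raw_ratio(coverage.entries.get(iid))
        for iid in catalog.interventions
    }

    def direct_resolution(iid):
        """(raw, provenance, source) for a direct intervention."""
        if own[iid] is not None:
            return own[iid], PROV_DIRECT, None
        backup = catalog.interventions[iid].channel.backup_id
        if backup is not None and own[backup] is not None:
            return own[backup], PROV_BACKUP, backup
        return None, PROV_UNAVAILABLE, None

    out = {}
    for iid, spec in catalog.interventions.items():
        ch = spec.channel
        if ch.kind == DIRECT:
            raw, prov, src = direct_resolution(iid)
        elif ch.kind == LINKED:
            raw, prov, src = direct_resolution(ch.parent_id)
            if raw is not None:
                prov, src = PROV_PROXY, ch.parent_id
        else:  # proxied
            raw, prov, src = direct_resolution(ch.source_id)
            if raw is not None:
                prov, src = PROV_PROXY, ch.source_id
            elif ch.backup_id is not None and own[ch.backup_id] is not None:
                raw, prov, src = own[ch.backup_id], PROV_BACKUP, ch.backup_id
        out[iid] = InequalityRatio(
            intervention_id=iid,
            raw_ratio=raw,
            applied_ratio=None if raw is None else max(raw, 1.0),
            provenance=prov,
            source_id=src,
        )
    return out


def ratios_to_frame(ratios_by_country: Mapping[str, Mapping[str, InequalityRatio]]) -> pd.DataFrame:
    """Flatten ``{country_id: {intervention_id: InequalityRatio}}`` to a tidy table."""
    rows = []
    for cid, ratios in ratios_by_country.items():
        for iid, r in ratios.items():
            prov = r.provenance if r.source_id is None else f"{r.provenance}({r.source_id})"
            rows.append({
                "country_id": cid,
                "intervention_id": iid,
                "raw_ratio": r.raw_ratio,
                "applied_ratio": r.applied_ratio,
                "provenance": prov,
            })
    return pd.DataFrame(rows, columns=[
        "country_id", "intervention_id", "raw_ratio", "applied_ratio", "provenance",
    ])


def write_ratios(ratios_by_country, path) -> None:
    ratios_to_frame(ratios_by_country).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """Paired baseline/target national coverage for one country.

    Baseline holds the latest national rates; targets multiply each in-scope
    intervention's baseline by its applied inequality ratio, capped at 1.
    Linked components carry no entries of their own — their coverage follows
    their parent contact point inside the impact engine.  ``cpr_scaled`` records
    whether contraceptive prevalence was scaled (only when the country's
    fertility exceeds the catalog's replacement-level gate).
    """

    country_id: str
    mode: str  # full | limited | single
    baseline_coverage: Mapping[str, float]
    target_coverage: Mapping[str, float]
    cpr_scaled: bool = False
    single_id: Optional[str] = None

    def __post_init__(self):
        assert set(self.baseline_coverage) == set(self.target_coverage)
        for iid, b in self.baseline_coverage.items():
            t = self.target_coverage[iid]
            assert 0.0 <= b <= 1.0 and 0.0 <= t <= 1.0, (iid, b, t)
            assert t >= b - 1e-12, f"target below baseline for {iid}"

    @property
    def scaled_interventions(self) -> frozenset:
        """Interventions whose target strictly exceeds baseline."""
        return frozenset(
            i for i, b in self.baseline_coverage.items()
            if self.target_coverage[i] > b
        )


def _scope(catalog: InterventionCatalog, mode: str, single_id: Optional[str]) -> set:
    """Interventions eligible for scale-up under a mode (ids whose own entry moves;
    linked children follow their parent implicitly)."""
    parents = catalog.coverage_only_parents
    if mode == FULL:
        return set(catalog.interventions)
    if mode == LIMITED:
        # directly measured interventions plus the contact points whose linked
        # components move with them; proxied interventions stay at baseline
        return {
            i for i, s in catalog.interventions.items()
            if s.channel.kind in (DIRECT, LINKED)
        }
    if mode == SINGLE:
        if single_id not in catalog.interventions:
            raise KeyError(f"unknown intervention {single_id!r}")
        if catalog.interventions[single_id].channel.kind == LINKED:
            raise ValueError(
                f"{single_id!r} is a linked component; scale its parent contact "
                f"point {catalog.interventions[single_id].channel.parent_id!r} instead"
            )
        return {single_id}
    raise ValueError(f"unknown mode {mode!r}")


def build_scenario(
    profile: CountryProfile,
    coverage: CoverageTable,
    catalog: InterventionCatalog,
    mode: str = FULL,
    single_id: Optional[str] = None,
    ratios: Optional[Mapping[str, InequalityRatio]] = None,
) -> Scenario:
    """Construct the baseline→top-quintile scale-up scenario for one country.

    Baseline coverage is each intervention's national rate; the target is
    baseline × applied ratio, capped at 1.  Scope: ``full`` scales every
    catalog item, ``limited`` only directly measured interventions and their
    linked components, ``single`` one intervention (a contact point moves its
    linked bundle).  Contraceptive prevalence is scaled only when the country's
    total fertility rate exceeds ``catalog.fertility_gate``.
    """
    if ratios is None:
        ratios = resolve_ratios(coverage, catalog)
    scope = _scope(catalog, mode, single_id)
    cpr_id = catalog.cpr_id

    baseline = {}
    target = {}
    cpr_scaled = False
    for iid, spec in catalog.interventions.items():
        if spec.channel.kind == LINKED:
            continue  # driven by parent inside the engine
        entry = coverage.entries.get(iid)
        base = entry.national if entry is not None else None
        if base is None:
            if iid in scope:
                logger.info("%s: no national coverage for %s; kept out of scenario",
                            profile.country_id, iid)
            continue
        baseline[iid] = base
        tgt = base
        if iid in scope:
            r = ratios.get(iid)
            if r is None or not r.available:
                logger.info("%s: no usable inequality ratio for %s; kept at baseline",
                            profile.country_id, iid)
            elif iid == cpr_id:
                if profile.tfr > catalog.fertility_gate:
                    tgt = min(base * r.applied_ratio, 1.0)
                    cpr_scaled = tgt > base
            else:
                tgt = min(base * r.applied_ratio, 1.0)
        target[iid] = tgt

    return Scenario(
        country_id=profile.country_id,
        mode=mode,
        baseline_coverage=baseline,
        target_coverage=target,
        cpr_scaled=cpr_scaled,
        single_id=single_id,
    )
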