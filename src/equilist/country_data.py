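"""Domain types for country epidemiology, quintile coverage, and the intervention catalog.

The central objects are:

* :class:`CountryProfile` — demography and baseline epidemiology of one country
  (annual live births, neonatal and post-neonatal mortality rates, cause-of-death
  fractions per age band, total fertility rate).
* :class:`CoverageTable` — per-intervention national coverage and coverage by
  wealth quintile from one household survey.  Missing cells are first-class:
  a blank is *not* zero, and downstream proxy/backup resolution depends on
  presence, not value.
* :class:`InterventionCatalog` — the set of modelled interventions with their
  delivery channel (directly survey-measured, linked to a measured contact point
  such as facility delivery, or proxied by a co-delivered measured intervention)
  and their effectiveness × affected-fraction entries per cause and age band.

CSV/JSON readers validate every invariant and reject bad rows with itemized
messages; round-trips are lossless including missingness.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

NEONATAL = "neonatal"
POSTNEONATAL = "postneonatal"
AGE_BANDS = (NEONATAL, POSTNEONATAL)

#: Default cause lists (user-extensible through the catalog file).
DEFAULT_NEONATAL_CAUSES = (
    "prematurity",
    "intrapartum",
    "sepsis_pneumonia",
    "congenital",
    "tetanus",
    "other_neonatal",
)
DEFAULT_POSTNEONATAL_CAUSES = (
    "pneumonia",
    "diarrhea",
    "malaria",
    "measles",
    "injury",
    "other_postneonatal",
)

_FRACTION_TOL = 1e-9


# ---------------------------------------------------------------------------
# Country profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountryProfile:
    """Demography and baseline epidemiology of one country.

    Mortality rates are deaths per 1000 live births; cause fractions are
    proportions summing to one within each age band.
    """

    country_id: str
    live_births: float
    nmr: float
    post_nmr: float
    tfr: float
    neonatal_cause_fractions: Mapping[str, float]
    postneonatal_cause_fractions: Mapping[str, float]
    survey_year: int

    def validate(self) -> None:
        msgs = []
        if not self.live_births > 0:
            msgs.append(f"live_births must be > 0, got {self.live_births}")
        if self.nmr < 0:
            msgs.append(f"nmr must be >= 0, got {self.nmr}")
        if self.post_nmr < 0:
            msgs.append(f"post_nmr must be >= 0, got {self.post_nmr}")
        if not self.tfr > 0:
            msgs.append(f"tfr must be > 0, got {self.tfr}")
        for band, fracs in (
            (NEONATAL, self.neonatal_cause_fractions),
            (POSTNEONATAL, self.postneonatal_cause_fractions),
        ):
            for cause, f in fracs.items():
                if not (0.0 <= f <= 1.0):
                    msgs.append(f"{band} fraction for {cause} outside [0,1]: {f}")
            total = sum(fracs.values())
            if abs(total - 1.0) > _FRACTION_TOL:
                msgs.append(f"{band} cause fractions sum to {total:.6g}, expected 1")
        if msgs:
            raise ValidationError([f"country {self.country_id}: {m}" for m in msgs])

    @property
    def u5_deaths(self) -> float:
        """Implied annual under-five deaths (neonatal + post-neonatal by construction)."""
        return self.live_births * (self.nmr + self.post_nmr) / 1000.0


# ---------------------------------------------------------------------------
# Coverage tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoverageEntry:
    """National and quintile coverage for one intervention; ``None`` marks missing.

    ``by_quintile`` is ordered poorest (q1) to richest (q5).
    """

    national: Optional[float] = None
    by_quintile: Optional[tuple] = None  # 5-tuple of Optional[float]

    @property
    def top_quintile(self) -> Optional[float]:
        if self.by_quintile is None:
            return None
        return self.by_quintile[4]

    def validate(self, label: str = "") -> None:
        msgs = []
        values = [("national", self.national)]
        if self.by_quintile is not None:
            if len(self.by_quintile) != 5:
                msgs.append(f"by_quintile must have 5 entries, got {len(self.by_quintile)}")
            values += [(f"q{i + 1}", v) for i, v in enumerate(self.by_quintile)]
        for name, v in values:
            if v is not None and not (0.0 <= v <= 1.0):
                msgs.append(f"{name} coverage outside [0,1]: {v}")
        if msgs:
            raise ValidationError([f"{label}: {m}" for m in msgs])
        # plausibility: national should sit within the quintile span (warn only)
        if self.national is not None and self.by_quintile is not None:
            present = [v for v in self.by_quintile if v is not None]
            if present and not (
                min(present) - 0.05 <= self.national <= max(present) + 0.05
            ):
                logger.warning(
                    "%s: national coverage %.3f outside quintile span [%.3f, %.3f]",
                    label, self.national, min(present), max(present),
                )


@dataclass
class CoverageTable:
    """Per-intervention coverage from one survey for one country."""

    country_id: str
    entries: dict = field(default_factory=dict)  # intervention_id -> CoverageEntry

    def validate(self, known_ids: Optional[Iterable[str]] = None) -> None:
        known = set(known_ids) if known_ids is not None else None
        for iid, entry in self.entries.items():
            entry.validate(label=f"{self.country_id}/{iid}")
            if known is not None and iid not in known:
                logger.warning(
                    "%s: unknown intervention_id %r kept; catalog decides usability",
                    self.country_id, iid,
                )


# ---------------------------------------------------------------------------
# Intervention catalog
# ---------------------------------------------------------------------------

DIRECT = "direct"
LINKED = "linked"
PROXIED = "proxied"


@dataclass(frozen=True)
class Channel:
    """How an intervention's coverage is observed.

    * ``direct`` — measured in household surveys; may name a ``backup`` whose
      inequality ratio stands in when this survey lacks the indicator.
    * ``linked(parent)`` — a component of care whose coverage is driven by a
      measured contact point (antenatal care, facility delivery).
    * ``proxied(source)`` — never survey-measured; adopts the inequality ratio
      of a co-delivered measured intervention.
    """

    kind: str  # direct | linked | proxied
    parent_id: Optional[str] = None  # linked: driving contact point
    source_id: Optional[str] = None  # proxied: ratio donor
    backup_id: Optional[str] = None  # fallback ratio donor (one level only)

    def __post_init__(self):
        if self.kind not in (DIRECT, LINKED, PROXIED):
            raise ValidationError(f"unknown channel kind {self.kind!r}")
        if self.kind == LINKED and not self.parent_id:
            raise ValidationError("linked channel requires parent_id")
        if self.kind == PROXIED and not self.source_id:
            raise ValidationError("proxied channel requires source_id")


@dataclass(frozen=True)
class Effect:
    """One effectiveness entry: proportional mortality reduction for a cause/age band."""

    cause: str
    age_band: str
    effectiveness: float
    affected_fraction: float

    def validate(self, label: str) -> None:
        msgs = []
        if self.age_band not in AGE_BANDS:
            msgs.append(f"age_band must be one of {AGE_BANDS}, got {self.age_band!r}")
        if not (0.0 <= self.effectiveness <= 1.0):
            msgs.append(f"effectiveness outside [0,1]: {self.effectiveness}")
        if not (0.0 <= self.affected_fraction <= 1.0):
            msgs.append(f"affected_fraction outside [0,1]: {self.affected_fraction}")
        if msgs:
            raise ValidationError([f"{label}: {m}" for m in msgs])

    @property
    def impact(self) -> float:
        return self.effectiveness * self.affected_fraction


@dataclass(frozen=True)
class InterventionSpec:
    intervention_id: str
    name: str
    channel: Channel
    effects: tuple = ()  # tuple[Effect, ...]
    is_cpr: bool = False
    group: str = "other"


@dataclass
class InterventionCatalog:
    """All modelled interventions plus contraception parameters.

    ``cpr_effectiveness`` is the use-effectiveness of contraception (proportional
    reduction in fecund exposure among users); ``fertility_gate`` is the total
    fertility rate above which contraceptive prevalence is scaled up (replacement
    level, default 2.33 children per woman).
    """

    interventions: dict  # intervention_id -> InterventionSpec
    cpr_effectiveness: float = 0.9
    fertility_gate: float = 2.33
    neonatal_causes: tuple = DEFAULT_NEONATAL_CAUSES
    postneonatal_causes: tuple = DEFAULT_POSTNEONATAL_CAUSES

    def __post_init__(self):
        self.validate()

    # -- views ------------------------------------------------------------

    @property
    def cpr_id(self) -> str:
        return next(i for i, s in self.interventions.items() if s.is_cpr)

    @property
    def coverage_only_parents(self) -> frozenset:
        """Contact points (ANC, SBA, facility delivery) that only drive linked
        components and have no effects of their own."""
        # direct, no effects, no fertility role: ANC and facility delivery (which
        # drive linked components) and skilled birth attendant (tracked alongside
        # them but with no children in the default catalog)
        return frozenset(
            i for i, s in self.interventions.items()
            if s.channel.kind == DIRECT and not s.effects and not s.is_cpr
        )

    def linked_children(self, parent_id: str) -> list:
        return [
            i for i, s in self.interventions.items()
            if s.channel.kind == LINKED and s.channel.parent_id == parent_id
        ]

    def scaled_ids(self) -> list:
        """Interventions counted as scale-up items: everything except the
        coverage-only contact points."""
        parents = self.coverage_only_parents
        return [i for i in self.interventions if i not in parents]

    def causes(self, age_band: str) -> tuple:
        return self.neonatal_causes if age_band == NEONATAL else self.postneonatal_causes

    def effects_on(self, cause: str, age_band: str) -> list:
        """(intervention_id, Effect) pairs acting on one cause-cell, catalog order."""
        out = []
        for iid, spec in self.interventions.items():
            for eff in spec.effects:
                if eff.cause == cause and eff.age_band == age_band:
                    out.append((iid, eff))
        return out

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        msgs = []
        if not (0.0 < self.cpr_effectiveness <= 1.0):
            msgs.append(f"cpr_effectiveness outside (0,1]: {self.cpr_effectiveness}")
        if not self.fertility_gate > 0:
            msgs.append(f"fertility_gate must be > 0, got {self.fertility_gate}")
        n_cpr = sum(1 for s in self.interventions.values() if s.is_cpr)
        if n_cpr != 1:
            msgs.append(f"exactly one intervention must have is_cpr, found {n_cpr}")
        valid_causes = set(self.neonatal_causes) | set(self.postneonatal_causes)
        for iid, spec in self.interventions.items():
            ch = spec.channel
            for ref, role in (
                (ch.parent_id, "linked parent"),
                (ch.source_id, "proxy source"),
                (ch.backup_id, "backup source"),
            ):
                if ref is None:
                    continue
                if ref == iid:
                    msgs.append(f"{iid}: {role} refers to itself")
                elif ref not in self.interventions:
                    msgs.append(f"{iid}: {role} {ref!r} not in catalog")
                elif self.interventions[ref].channel.kind != DIRECT:
                    msgs.append(f"{iid}: {role} {ref!r} must be channel=direct")
            for eff in spec.effects:
                eff.validate(label=iid)
                band_causes = self.causes(eff.age_band)
                if eff.cause not in valid_causes:
                    msgs.append(f"{iid}: unknown cause {eff.cause!r}")
                elif eff.cause not in band_causes:
                    msgs.append(f"{iid}: cause {eff.cause!r} not in {eff.age_band} band")
        if msgs:
            raise ValidationError(msgs)


# ---------------------------------------------------------------------------
# Catalog I/O
# ---------------------------------------------------------------------------


def _spec_from_dict(d: Mapping) -> InterventionSpec:
    ch = d.get("channel", "direct")
    if isinstance(ch, str):
        channel = Channel(kind=ch, backup_id=d.get("backup"))
    else:
        kind = ch.get("kind", DIRECT)
        channel = Channel(
            kind=kind,
            parent_id=ch.get("parent"),
            source_id=ch.get("source"),
            backup_id=ch.get("backup", d.get("backup")),
        )
    effects = tuple(
        Effect(
            cause=e["cause"],
            age_band=e["age_band"],
            effectiveness=float(e["effectiveness"]),
            affected_fraction=float(e["affected_fraction"]),
        )
        for e in d.get("effects", []) or []
    )
    return InterventionSpec(
        intervention_id=d["id"],
        name=d.get("name", d["id"]),
        channel=channel,
        effects=effects,
        is_cpr=bool(d.get("is_cpr", False)),
        group=d.get("group", "other"),
    )


def load_catalog(path) -> InterventionCatalog:
    """Load an intervention catalog from a YAML (or JSON) file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return catalog_from_dict(doc)


def catalog_from_dict(doc: Mapping) -> InterventionCatalog:
    interventions = {}
    for d in doc["interventions"]:
        spec = _spec_from_dict(d)
        if spec.intervention_id in interventions:
            raise ValidationError(f"duplicate intervention_id {spec.intervention_id!r}")
        interventions[spec.intervention_id] = spec
    kwargs = {}
    if "neonatal_causes" in doc:
        kwargs["neonatal_causes"] = tuple(doc["neonatal_causes"])
    if "postneonatal_causes" in doc:
        kwargs["postneonatal_causes"] = tuple(doc["postneonatal_causes"])
    return InterventionCatalog(
        interventions=interventions,
        cpr_effectiveness=float(doc.get("cpr_effectiveness", 0.9)),
        fertility_gate=float(doc.get("fertility_gate", 2.33)),
        **kwargs,
    )


def default_catalog() -> InterventionCatalog:
    """The shipped 41-row catalog: 38 scale-up items plus the three coverage-only
    contact points (antenatal care, skilled birth attendant, facility delivery).

    Delivery channels and proxy/backup links reflect how intervention packages
    are co-delivered; effectiveness and affected-fraction values are shipped
    package defaults with plausible magnitudes, not authoritative estimates,
    and can be overridden via :func:`load_catalog`.
    """
    ref = resources.files("equilist").joinpath("data/default_catalog.yaml")
    with resources.as_file(ref) as path:
        return load_catalog(path)


# ---------------------------------------------------------------------------
# Country profile I/O
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = ("country_id", "survey_year", "live_births", "nmr", "post_nmr", "tfr")


def _profile_from_record(rec: Mapping, ncauses: Sequence[str], pcauses: Sequence[str]) -> CountryProfile:
    return CountryProfile(
        country_id=str(rec["country_id"]),
        live_births=float(rec["live_births"]),
        nmr=float(rec["nmr"]),
        post_nmr=float(rec["post_nmr"]),
        tfr=float(rec["tfr"]),
        survey_year=int(rec["survey_year"]),
        neonatal_cause_fractions={c: float(rec[f"ncause_{c}"]) for c in ncauses},
        postneonatal_cause_fractions={c: float(rec[f"pcause_{c}"]) for c in pcauses},
    )


def read_country_profiles(path, format: Optional[str] = None) -> list:
    """Read country profiles from ``countries.csv`` (or its JSON mirror).

    Every profile is validated; a row violating an invariant raises
    :class:`ValidationError` with itemized messages.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        with open(path) as fh:
            records = json.load(fh)
        if not isinstance(records, list):
            raise SchemaError(f"{path}: expected a JSON array of country records")
        columns = set().union(*(r.keys() for r in records)) if records else set()
    elif fmt == "csv":
        df = pd.read_csv(path)
        records = df.to_dict(orient="records")
        columns = set(df.columns)
    else:
        raise SchemaError(f"unknown format {fmt!r}")

    missing = [c for c in _PROFILE_COLUMNS if c not in columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    ncauses = sorted(c[len("ncause_"):] for c in columns if c.startswith("ncause_"))
    pcauses = sorted(c[len("pcause_"):] for c in columns if c.startswith("pcause_"))
    if not ncauses or not pcauses:
        raise SchemaError(f"{path}: need at least one ncause_* and one pcause_* column")

    profiles = []
    for rec in records:
        profile = _profile_from_record(rec, ncauses, pcauses)
        profile.validate()
        profiles.append(profile)
    return profiles


def write_country_profiles(profiles: Sequence[CountryProfile], path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    ncauses = sorted({c for p in profiles for c in p.neonatal_cause_fractions})
    pcauses = sorted({c for p in profiles for c in p.postneonatal_cause_fractions})
    records = []
    for p in profiles:
        rec = {
            "country_id": p.country_id,
            "survey_year": p.survey_year,
            "live_births": p.live_births,
            "nmr": p.nmr,
            "post_nmr": p.post_nmr,
            "tfr": p.tfr,
        }
        rec.update({f"ncause_{c}": p.neonatal_cause_fractions.get(c, 0.0) for c in ncauses})
        rec.update({f"pcause_{c}": p.postneonatal_cause_fractions.get(c, 0.0) for c in pcauses})
        records.append(rec)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        pd.DataFrame.from_records(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Coverage table I/O
# ---------------------------------------------------------------------------

_COVERAGE_COLUMNS = ("country_id", "intervention_id", "national", "q1", "q2", "q3", "q4", "q5")


def _cell(value, percent: bool) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    v = float(value)
    return v / 100.0 if percent else v


def read_coverage_tables(path, percent: bool = False,
                         known_ids: Optional[Iterable[str]] = None) -> dict:
    """Read a long-form ``coverage.csv`` into ``{country_id: CoverageTable}``.

    Empty cells stay missing (never imputed as zero).  With ``percent=True``
    values are given on the 0–100 scale and divided by 100 on read.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        columns = set().union(*(r.keys() for r in records)) if records else set()
    else:
        df = pd.read_csv(path)
        records = df.to_dict(orient="records")
        columns = set(df.columns)
    missing = [c for c in _COVERAGE_COLUMNS[:2] if c not in columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    tables: dict = {}
    for rec in records:
        cid = str(rec["country_id"])
        iid = str(rec["intervention_id"])
        quintiles = tuple(_cell(rec.get(f"q{i}"), percent) for i in range(1, 6))
        entry = CoverageEntry(
            national=_cell(rec.get("national"), percent),
            by_quintile=None if all(q is None for q in quintiles) else quintiles,
        )
        entry.validate(label=f"{cid}/{iid}")
        tables.setdefault(cid, CoverageTable(country_id=cid)).entries[iid] = entry
    for table in tables.values():
        table.validate(known_ids=known_ids)
    return tables


def read_coverage_table(path, country_id: Optional[str] = None, percent: bool = False,
                        known_ids: Optional[Iterable[str]] = None) -> CoverageTable:
    """Read one country's coverage table; the file must contain a single country
    unless ``country_id`` selects one."""
    tables = read_coverage_tables(path, percent=percent, known_ids=known_ids)
    if country_id is not None:
        if country_id not in tables:
            raise SchemaError(f"{path}: no rows for country {country_id!r}")
        return tables[country_id]
    if len(tables) != 1:
        raise SchemaError(
            f"{path}: contains {len(tables)} countries; pass country_id to select one"
        )
    return next(iter(tables.values()))


def write_coverage_tables(tables: Iterable[CoverageTable], path) -> None:
    path = Path(path)
    records = []
    for table in tables:
        for iid, e in table.entries.items():
            quintiles = e.by_quintile or (None,) * 5
            rec = {"country_id": table.country_id, "intervention_id": iid,
                   "national": e.national}
            rec.update({f"q{i + 1}": quintiles[i] for i in range(5)})
            records.append(rec)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
    else:
        pd.DataFrame.from_records(records, columns=_COVERAGE_COLUMNS).to_csv(path, index=False)
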