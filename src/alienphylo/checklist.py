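"""Checklist data model, validation, status algebra and tabulations.

A checklist is a table of alien species, one row per species, recording
taxonomy (family, genus), lifeform, native origin region(s) under the TDWG
level-1 scheme, introduction pathway, and the highest invasion stage the
species has attained (casual < naturalized < invasive).  The stage column
stores only the highest stage; the five nested assemblages used throughout
the analysis (alien ⊇ naturalized ⊇ invasive, plus the casual and NNI
differences) are derived, never stored, so inconsistent flags cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ChecklistError

#: Invasion stages, lowest to highest.
STATUSES = ("casual", "naturalized", "invasive")

#: Lifeform categories kept after input mapping; "biennial" survives reading
#: and is folded into "perennial" only by :func:`normalize_lifeform`.
LIFEFORMS = ("annual", "biennial", "perennial", "woody", "other")

PATHWAYS = (
    "ornamental",
    "forage",
    "medicinal",
    "food",
    "unintentional",
    "natural",
    "unknown",
    "other",
)

#: TDWG level-1 continental units (plus "unknown" for unplaced origins).
TDWG_REGIONS = (
    "africa",
    "america",
    "australasia",
    "europe",
    "pacific",
    "temperate asia",
    "tropical asia",
    "antarctic",
    "unknown",
)

#: Default mapping of extra lifeform tokens accepted on read.  Woody growth
#: forms collapse to "woody"; aquatics and anything else unclassifiable to
#: "other".  Override via the ``lifeform_map`` argument of
#: :func:`read_checklist`.
DEFAULT_LIFEFORM_MAP: Mapping[str, str] = {
    "vine": "woody",
    "liana": "woody",
    "shrub": "woody",
    "tree": "woody",
    "aquatic": "other",
}

REQUIRED_COLUMNS = ("species", "family", "genus", "lifeform", "origin", "pathway", "status")


@dataclass(frozen=True)
class SpeciesRecord:
    """One checklist row.

    ``status`` encodes the highest attained invasion stage; membership in the
    lower stages is implied by nesting and derived by
    :func:`derive_assemblages`.
    """

    species_name: str
    family: str
    genus: str
    lifeform: str
    origins: frozenset[str]
    pathway: str
    status: str

    def __post_init__(self):
        if not self.species_name:
            raise ChecklistError("species_name must be non-empty")
        if self.lifeform not in LIFEFORMS:
            raise ChecklistError(
                f"unknown lifeform {self.lifeform!r}; allowed: {', '.join(LIFEFORMS)}"
            )
        if self.pathway not in PATHWAYS:
            raise ChecklistError(
                f"unknown pathway {self.pathway!r}; allowed: {', '.join(PATHWAYS)}"
            )
        if self.status not in STATUSES:
            raise ChecklistError(
                f"unknown status {self.status!r}; allowed: {', '.join(STATUSES)}"
            )
        if not self.origins:
            raise ChecklistError(f"{self.species_name}: origins must be non-empty")
        bad = sorted(set(self.origins) - set(TDWG_REGIONS))
        if bad:
            raise ChecklistError(
                f"{self.species_name}: unknown origin region(s) {bad}; "
                f"allowed: {', '.join(TDWG_REGIONS)}"
            )


@dataclass(frozen=True)
class Checklist:
    """An ordered collection of species records with unique names."""

    records: tuple[SpeciesRecord, ...]

    def __post_init__(self):
        seen: dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.species_name in seen:
                raise ChecklistError(
                    f"duplicate species {rec.species_name!r} "
                    f"(records {seen[rec.species_name] + 1} and {i + 1})"
                )
            seen[rec.species_name] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(r.species_name for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; ``origin`` is a semicolon-joined sorted region list."""
        return pd.DataFrame(
            {
                "species": [r.species_name for r in self.records],
                "family": [r.family for r in self.records],
                "genus": [r.genus for r in self.records],
                "lifeform": [r.lifeform for r in self.records],
                "origin": [";".join(sorted(r.origins)) for r in self.records],
                "pathway": [r.pathway for r in self.records],
                "status": [r.status for r in self.records],
            }
        )


@dataclass(frozen=True)
class AssemblageSet:
    """The five nested species sets derived from the status column.

    Invariants enforced on construction: invasive ⊆ naturalized ⊆ alien,
    casual = alien \\ naturalized, nni = naturalized \\ invasive.
    """

    alien: frozenset[str]
    casual: frozenset[str]
    naturalized: frozenset[str]
    nni: frozenset[str]
    invasive: frozenset[str]

    #: Stable order used for per-assemblage sub-seeds and reports.
    NAMES = ("alien", "casual", "naturalized", "nni", "invasive")

    def __post_init__(self):
        if not self.invasive <= self.naturalized <= self.alien:
            raise ChecklistError("nesting violated: invasive ⊆ naturalized ⊆ alien required")
        if self.casual != self.alien - self.naturalized:
            raise ChecklistError("casual must equal alien minus naturalized")
        if self.nni != self.naturalized - self.invasive:
            raise ChecklistError("nni must equal naturalized minus invasive")

    def __getitem__(self, name: str) -> frozenset[str]:
        if name not in self.NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def sizes(self) -> dict[str, int]:
        return {name: len(self[name]) for name in self.NAMES}


def _canon(token: str) -> str:
    return " ".join(str(token).strip().lower().split())


def read_checklist(
    path: str | Path,
    *,
    lifeform_map: Mapping[str, str] | None = None,
    **read_csv_kwargs,
) -> Checklist:
    """Read and validate a checklist CSV.

    The file must be UTF-8, comma-delimited, with header columns
    ``species,family,genus,lifeform,origin,pathway,status``; ``origin`` is a
    semicolon-separated list of TDWG level-1 region names.  Tokens are
    case-insensitive and canonicalized to lower case.  Extra lifeform tokens
    (vine, shrub, tree, aquatic, ...) are folded into the core categories via
    ``lifeform_map`` (default :data:`DEFAULT_LIFEFORM_MAP`).  Biennial →
    perennial folding is *not* applied here; see :func:`normalize_lifeform`.

    Raises :class:`ChecklistError` listing offending row numbers (1-based,
    excluding the header) for unknown tokens, duplicates or missing columns.
    """
    path = Path(path)
    if not path.exists():
        raise ChecklistError(f"checklist file not found: {path}")
    lf_map = dict(DEFAULT_LIFEFORM_MAP if lifeform_map is None else lifeform_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, **read_csv_kwargs)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ChecklistError(f"missing required column(s): {', '.join(missing)}")

    records: list[SpeciesRecord] = []
    problems: list[str] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        name = " ".join(str(getattr(row, "species")).strip().split())
        if not name:
            problems.append(f"row {i}: empty species name")
            continue
        if name in seen:
            problems.append(f"row {i}: duplicate species {name!r} (first at row {seen[name]})")
            continue
        seen[name] = i
        lifeform = _canon(getattr(row, "lifeform"))
        lifeform = lf_map.get(lifeform, lifeform)
        pathway = _canon(getattr(row, "pathway"))
        status = _canon(getattr(row, "status"))
        origins = frozenset(
            _canon(tok) for tok in str(getattr(row, "origin")).split(";") if tok.strip()
        )
        row_errs = []
        if lifeform not in LIFEFORMS:
            row_errs.append(f"lifeform {lifeform!r} (allowed: {', '.join(LIFEFORMS)})")
        if pathway not in PATHWAYS:
            row_errs.append(f"pathway {pathway!r} (allowed: {', '.join(PATHWAYS)})")
        if status not in STATUSES:
            row_errs.append(f"status {status!r} (allowed: {', '.join(STATUSES)})")
        if not origins:
            row_errs.append("empty origin")
        else:
            bad = sorted(origins - set(TDWG_REGIONS))
            if bad:
                row_errs.append(f"origin region(s) {bad} (allowed: {', '.join(TDWG_REGIONS)})")
        if row_errs:
            problems.append(f"row {i}: " + "; ".join(row_errs))
            continue
        records.append(
            SpeciesRecord(
                species_name=name,
                family=_canon(getattr(row, "family")).title(),
                genus=_canon(getattr(row, "genus")).title(),
                lifeform=lifeform,
                origins=origins,
                pathway=pathway,
                status=status,
            )
        )
    if problems:
        raise ChecklistError("invalid checklist:\n  " + "\n  ".join(problems))
    return Checklist(records=tuple(records))


def write_checklist(checklist: Checklist, path: str | Path) -> None:
    """Write a checklist back to the CSV interchange format."""
    checklist.to_frame().to_csv(path, index=False)


def normalize_lifeform(record: SpeciesRecord) -> SpeciesRecord:
    """Fold biennials into perennials (the two are pooled for analysis).

    Idempotent; every other lifeform is returned unchanged.
    """
    if record.lifeform == "biennial":
        return replace(record, lifeform="perennial")
    return record


def normalize_checklist(checklist: Checklist) -> Checklist:
    """Apply :func:`normalize_lifeform` to every record."""
    return Checklist(records=tuple(normalize_lifeform(r) for r in checklist))


def derive_assemblages(checklist: Checklist) -> AssemblageSet:
    """Derive the five nested assemblages from the highest-stage status column.

    alien = every species; naturalized = status ∈ {naturalized, invasive};
    invasive = status invasive; casual and NNI by set difference.
    """
    alien = frozenset(checklist.species_names)
    naturalized = frozenset(
        r.species_name for r in checklist if r.status in ("naturalized", "invasive")
    )
    invasive = frozenset(r.species_name for r in checklist if r.status == "invasive")
    return AssemblageSet(
        alien=alien,
        casual=alien - naturalized,
        naturalized=naturalized,
        nni=naturalized - invasive,
        invasive=invasive,
    )


TABULATION_FIELDS = ("family", "lifeform", "origin", "pathway")


def tabulate_by(
    checklist: Checklist,
    field_name: str,
    assemblage: Iterable[str],
) -> pd.DataFrame:
    """Count and proportion table of ``field_name`` over an assemblage.

    For family/lifeform/pathway each species contributes one count and the
    proportions sum to 1.  For origin a species contributes one count to EACH
    of its origin regions (TDWG regions are not exclusive for a species), so
    origin proportions may sum to more than 1; the denominator is always the
    assemblage size.

    Returns a DataFrame with columns ``category, count, proportion`` sorted by
    descending count then category.  Raises on an empty assemblage or on
    species missing from the checklist.
    """
    if field_name not in TABULATION_FIELDS:
        raise ChecklistError(
            f"unknown tabulation field {field_name!r}; allowed: {', '.join(TABULATION_FIELDS)}"
        )
    members = frozenset(assemblage)
    if not members:
        raise ChecklistError("cannot tabulate an empty assemblage")
    missing = members - set(checklist.species_names)
    if missing:
        raise ChecklistError(f"assemblage species not in checklist: {sorted(missing)[:5]}")

    counts: dict[str, int] = {}
    for rec in checklist:
        if rec.species_name not in members:
            continue
        if field_name == "origin":
            cats: Sequence[str] = sorted(rec.origins)
        else:
            cats = (getattr(rec, "family" if field_name == "family" else field_name),)
        for cat in cats:
            counts[cat] = counts.get(cat, 0) + 1
    n = len(members)
    out = pd.DataFrame(
        {"category": list(counts), "count": list(counts.values())}
    ).sort_values(["count", "category"], ascending=[False, True], ignore_index=True)
    out["proportion"] = out["count"] / n
    return out


@dataclass(frozen=True)
class FamilyTransitionRates:
    """Naturalization and invasion rates within one family.

    ``rate_nat`` = naturalized / alien; ``rate_inv`` = invasive / naturalized.
    A rate whose denominator is zero is undefined and reported as ``None``
    (never coerced to 0).
    """

    family: str
    n_alien: int
    n_naturalized: int
    n_invasive: int
    rate_nat: float | None = field(default=None)
    rate_inv: float | None = field(default=None)


def transition_rates(
    checklist: Checklist, families: Sequence[str] | None = None
) -> list[FamilyTransitionRates]:
    """Per-family stage-transition rates (alien→naturalized, naturalized→invasive).

    ``families=None`` covers every family in the checklist, ordered by
    descending alien richness.  Requesting a family absent from the checklist
    raises.
    """
    assem = derive_assemblages(checklist)
    by_family: dict[str, list[SpeciesRecord]] = {}
    for rec in checklist:
        by_family.setdefault(rec.family, []).append(rec)
    if families is None:
        families = sorted(by_family, key=lambda f: (-len(by_family[f]), f))
    else:
        absent = [f for f in families if f not in by_family]
        if absent:
            raise ChecklistError(f"families not present in checklist: {absent}")
    results = []
    for fam in families:
        names = {r.species_name for r in by_family.get(fam, [])}
        n_alien = len(names & assem.alien)
        n_nat = len(names & assem.naturalized)
        n_inv = len(names & assem.invasive)
        results.append(
            FamilyTransitionRates(
                family=fam,
                n_alien=n_alien,
                n_naturalized=n_nat,
                n_invasive=n_inv,
                rate_nat=(n_nat / n_alien) if n_alien else None,
                rate_inv=(n_inv / n_nat) if n_nat else None,
            )
        )
    return results
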