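"""Domain types, CSV record I/O and dataset validation.

All on-disk formats are UTF-8 CSV with a header row and ISO-8601 dates.
Species identifiers are opaque strings matched exactly (case-sensitive);
scientific-name mapping lives only in the trait table.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "SITES",
    "CITIES",
    "HABITATS",
    "STRATA",
    "MIGRATORY_CLASSES",
    "CollisionRecord",
    "ChecklistRecord",
    "SpeciesTraits",
    "NightRecord",
    "RowError",
    "ReadResult",
    "ValidationReport",
    "read_records",
    "write_records",
    "validate_dataset",
]

SITES = ("mccormick", "downtown", "other_city")
CITIES = ("chicago", "cleveland")
FLIGHT_CALL = ("yes", "no")
HABITATS = ("forest", "edge", "open")
STRATA = ("upper", "lower")
MIGRATORY_CLASSES = (
    "nocturnal_passerine",
    "diurnal_passerine",
    "resident",
    "nonpasserine",
)

MAX_LIGHT_SCORE = 17


@dataclass(frozen=True)
class CollisionRecord:
    """One monitored carcass."""

    species_id: str
    date: _dt.date
    site: str = "mccormick"
    city: str = "chicago"

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.city not in CITIES:
            raise ValueError(f"unknown city {self.city!r}")


@dataclass(frozen=True)
class ChecklistRecord:
    """One checklist reporting at least one individual of the species."""

    species_id: str
    date: _dt.date
    city: str = "chicago"

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if self.city not in CITIES:
            raise ValueError(f"unknown city {self.city!r}")


@dataclass(frozen=True)
class SpeciesTraits:
    """Per-species trait row: flight call, habitat, stratum, population, class."""

    species_id: str
    flight_call: str
    habitat: str
    stratum: str
    regional_pop_size: float
    migratory_class: str = "nocturnal_passerine"

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        if self.flight_call not in FLIGHT_CALL:
            raise ValueError(f"flight_call must be yes/no, got {self.flight_call!r}")
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if not self.regional_pop_size > 0:
            raise ValueError("regional_pop_size must be > 0")
        if self.migratory_class not in MIGRATORY_CLASSES:
            raise ValueError(f"unknown migratory_class {self.migratory_class!r}")


@dataclass(frozen=True)
class NightRecord:
    """One monitored night: light score (0-17 lit window bays) and collisions."""

    date: _dt.date
    light_score: int
    collisions_by_species: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.light_score <= MAX_LIGHT_SCORE:
            raise ValueError(
                f"light_score must be in [0, {MAX_LIGHT_SCORE}], got {self.light_score}"
            )
        for sp, n in self.collisions_by_species:
            if n < 0:
                raise ValueError(f"negative collision count for {sp!r}")

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.collisions_by_species)

    @property
    def total_collisions(self) -> int:
        return sum(n for _, n in self.collisions_by_species)


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


@dataclass
class ReadResult:
    """Parsed records plus row-level diagnostics for rejected rows."""

    records: list
    errors: list[RowError] = field(default_factory=list)

    def __iter__(self) -> Iterator:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


_HEADERS = {
    "collision": ["species_id", "date", "site", "city"],
    "checklist": ["species_id", "date", "city"],
    "traits": [
        "species_id",
        "flight_call",
        "habitat",
        "stratum",
        "regional_pop_size",
        "migratory_class",
    ],
    "nights": ["date", "light_score", "species_id", "count"],
}


def _parse_date(text: str) -> _dt.date:
    return _dt.date.fromisoformat(text)


def read_records(path: str | Path, schema: str) -> ReadResult:
    """Read one CSV file of the given record kind.

    ``schema`` is one of ``collision``, ``checklist``, ``traits``, ``nights``.
    Malformed rows are rejected individually and reported in ``.errors`` with
    their 1-based line number; well-formed rows are kept in file order.
    """
    if schema not in _HEADERS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_HEADERS)}")
    path = Path(path)
    expected = _HEADERS[schema]
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header {expected}")
        if [h.strip() for h in header] != expected:
            raise ValueError(f"{path}: header {header} does not match schema {expected}")
        rows = [(i, row) for i, row in enumerate(reader, start=2) if row]

    if schema == "nights":
        return _assemble_nights(rows)

    records: list = []
    errors: list[RowError] = []
    for lineno, row in rows:
        if len(row) != len(expected):
            errors.append(RowError(lineno, f"expected {len(expected)} fields, got {len(row)}"))
            continue
        try:
            records.append(_parse_row(schema, row))
        except ValueError as exc:
            errors.append(RowError(lineno, str(exc)))
    return ReadResult(records, errors)


def _parse_row(schema: str, row: list[str]):
    if schema == "collision":
        return CollisionRecord(row[0], _parse_date(row[1]), row[2], row[3])
    if schema == "checklist":
        return ChecklistRecord(row[0], _parse_date(row[1]), row[2])
    return SpeciesTraits(row[0], row[1], row[2], row[3], float(row[4]), row[5])


def _assemble_nights(rows: list[tuple[int, list[str]]]) -> ReadResult:
    # long form: one row per (night, species); a collision-free night is a
    # single row with empty species_id and count 0
    errors: list[RowError] = []
    nights: dict[_dt.date, tuple[int, list[tuple[str, int]]]] = {}
    order: list[_dt.date] = []
    for lineno, row in rows:
        if len(row) != 4:
            errors.append(RowError(lineno, f"expected 4 fields, got {len(row)}"))
            continue
        try:
            date = _parse_date(row[0])
            score = int(row[1])
            if not 0 <= score <= MAX_LIGHT_SCORE:
                raise ValueError(f"light_score {score} out of range 0-{MAX_LIGHT_SCORE}")
            count = int(row[3])
            if count < 0:
                raise ValueError(f"negative count {count}")
        except ValueError as exc:
            errors.append(RowError(lineno, str(exc)))
            continue
        if date not in nights:
            nights[date] = (score, [])
            order.append(date)
        elif nights[date][0] != score:
            errors.append(RowError(lineno, f"conflicting light_score for {date}"))
            continue
        if row[2]:
            nights[date][1].append((row[2], count))
    records = [
        NightRecord(d, nights[d][0], tuple(nights[d][1])) for d in order
    ]
    return ReadResult(records, errors)


def write_records(records: Iterable, schema: str, path: str | Path) -> None:
    """Write records to CSV; the exact inverse of :func:`read_records`."""
    if schema not in _HEADERS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_HEADERS[schema])
        for rec in records:
            if schema == "collision":
                writer.writerow([rec.species_id, rec.date.isoformat(), rec.site, rec.city])
            elif schema == "checklist":
                writer.writerow([rec.species_id, rec.date.isoformat(), rec.city])
            elif schema == "traits":
                writer.writerow(
                    [
                        rec.species_id,
                        rec.flight_call,
                        rec.habitat,
                        rec.stratum,
                        format(rec.regional_pop_size, "g"),
                        rec.migratory_class,
                    ]
                )
            else:  # nights
                if rec.collisions_by_species:
                    for sp, n in rec.collisions_by_species:
                        writer.writerow([rec.date.isoformat(), rec.light_score, sp, n])
                else:
                    writer.writerow([rec.date.isoformat(), rec.light_score, "", 0])


@dataclass
class ValidationReport:
    """Report-only dataset validation result; never mutates its inputs."""

    missing_species: list[str] = field(default_factory=list)
    duplicate_trait_species: list[str] = field(default_factory=list)
    out_of_window_records: int = 0

    @property
    def is_clean(self) -> bool:
        return (
            not self.missing_species
            and not self.duplicate_trait_species
            and self.out_of_window_records == 0
        )


def validate_dataset(
    records: Sequence,
    traits: Sequence[SpeciesTraits],
    season_windows=None,
) -> ValidationReport:
    """Cross-check records against the trait table.

    Reports species referenced by records but absent from the trait table,
    duplicated trait rows, and (if ``season_windows`` is given) records dated
    outside the monitoring windows.  Monitoring-window membership is a soft
    warning here; hard filtering happens in :mod:`collide.tallies`.
    """
    known: set[str] = set()
    dupes: list[str] = []
    for t in traits:
        if t.species_id in known and t.species_id not in dupes:
            dupes.append(t.species_id)
        known.add(t.species_id)

    missing: list[str] = []
    seen_missing: set[str] = set()
    n_outside = 0
    for rec in records:
        sid = getattr(rec, "species_id", None)
        if sid is not None and sid not in known and sid not in seen_missing:
            seen_missing.add(sid)
            missing.append(sid)
        if season_windows is not None:
            date = getattr(rec, "date", None)
            if date is not None and season_windows.assign(date) == "outside":
                n_outside += 1
    return ValidationReport(sorted(missing), sorted(dupes), n_outside)
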