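"""Inclusion filters and per-species, per-season tally indices.

Four indices per species and season: total collisions, unique collision
days, checklists, and unique checklist days.  The "days" variants compress
relative abundance (a species is counted at most once per date) and are the
basis of the second analysis mode.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .data_model import ChecklistRecord, CollisionRecord, SpeciesTraits

__all__ = ["SeasonWindows", "FilterResult", "filter_nocturnal_passerines", "assign_season", "tally", "TallyTable"]

SEASONS = ("spring", "autumn")


@dataclass(frozen=True)
class SeasonWindows:
    """Month/day boundaries of the two migration windows (year-agnostic).

    Spring defaults to 1 March - 31 May.  "Late August" onward is
    operationalized as 15 August - 30 November; both windows are
    configurable.
    """

    spring_start: tuple[int, int] = (3, 1)
    spring_end: tuple[int, int] = (5, 31)
    autumn_start: tuple[int, int] = (8, 15)
    autumn_end: tuple[int, int] = (11, 30)

    def assign(self, date: _dt.date) -> str:
        """Map a calendar date to ``spring``, ``autumn`` or ``outside``."""
        md = (date.month, date.day)
        if self.spring_start <= md <= self.spring_end:
            return "spring"
        if self.autumn_start <= md <= self.autumn_end:
            return "autumn"
        return "outside"

    def dates(self, season: str, year: int) -> list[_dt.date]:
        """All calendar dates of one season window in one year."""
        if season == "spring":
            start, end = self.spring_start, self.spring_end
        elif season == "autumn":
            start, end = self.autumn_start, self.autumn_end
        else:
            raise ValueError(f"unknown season {season!r}")
        d0 = _dt.date(year, *start)
        d1 = _dt.date(year, *end)
        return [d0 + _dt.timedelta(days=i) for i in range((d1 - d0).days + 1)]


DEFAULT_WINDOWS = SeasonWindows()


def assign_season(date: _dt.date, windows: SeasonWindows = DEFAULT_WINDOWS) -> str:
    return windows.assign(date)


@dataclass
class FilterResult:
    records: list
    excluded_by_class: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def filter_nocturnal_passerines(
    records: Sequence, traits: Sequence[SpeciesTraits]
) -> FilterResult:
    """Keep only records of nocturnally migrating passerine species.

    Diurnal migrants, residents and non-passerines are dropped; the counts
    of excluded records are reported per migratory class.  A record of a
    species with no trait row is an error.
    """
    class_of = {t.species_id: t.migratory_class for t in traits}
    unknown = sorted({r.species_id for r in records if r.species_id not in class_of})
    if unknown:
        raise ValueError(f"records reference species without trait rows: {unknown}")
    kept: list = []
    excluded: dict[str, int] = {}
    for rec in records:
        cls = class_of[rec.species_id]
        if cls == "nocturnal_passerine":
            kept.append(rec)
        else:
            excluded[cls] = excluded.get(cls, 0) + 1
    return FilterResult(kept, excluded)


@dataclass
class TallyTable:
    """Per-(species, season) tally indices as a tidy DataFrame.

    Columns: species_id, season, n_collisions, n_collision_days,
    n_checklists, n_checklist_days.  Seasons are ``spring``, ``autumn`` and
    ``pooled``; pooled rows sum the in-window seasons only (out-of-window
    records are excluded before tallying).
    """

    frame: pd.DataFrame

    def rows(self, season: str) -> pd.DataFrame:
        sub = self.frame[self.frame["season"] == season]
        return sub.set_index("species_id").drop(columns="season").sort_index()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TallyTable":
        return cls(pd.read_csv(path, dtype={"species_id": str}))


def tally(
    collisions: Iterable[CollisionRecord],
    checklists: Iterable[ChecklistRecord],
    species: Sequence[str],
    windows: SeasonWindows = DEFAULT_WINDOWS,
    season_split: bool = True,
    include_outside: bool = False,
) -> TallyTable:
    """Compute the four tally indices per species and season.

    ``species`` fixes the row universe: species present in the trait table
    but never recorded get explicit zero rows (they are informative cells of
    the goodness-of-fit test).  Records dated outside both windows are
    dropped unless ``include_outside`` is set, in which case they count only
    toward the pooled rows.
    """
    species = list(species)
    collisions = list(collisions)
    checklists = list(checklists)
    recorded = {r.species_id for r in collisions} | {r.species_id for r in checklists}
    species += sorted(recorded - set(species))
    seasons = list(SEASONS) if season_split else []

    ncol: dict[tuple[str, str], int] = {}
    col_days: dict[tuple[str, str], set] = {}
    nchk: dict[tuple[str, str], int] = {}
    chk_days: dict[tuple[str, str], set] = {}

    def _bump(count, days, rec):
        season = windows.assign(rec.date)
        if season == "outside" and not include_outside:
            return
        for key in ([season] if season != "outside" else []) + ["pooled"]:
            k = (rec.species_id, key)
            count[k] = count.get(k, 0) + 1
            days.setdefault(k, set()).add(rec.date)

    for rec in collisions:
        _bump(ncol, col_days, rec)
    for rec in checklists:
        _bump(nchk, chk_days, rec)

    rows = []
    for sp in species:
        for season in seasons + ["pooled"]:
            k = (sp, season)
            rows.append(
                {
                    "species_id": sp,
                    "season": season,
                    "n_collisions": ncol.get(k, 0),
                    "n_collision_days": len(col_days.get(k, ())),
                    "n_checklists": nchk.get(k, 0),
                    "n_checklist_days": len(chk_days.get(k, ())),
                }
            )
    return TallyTable(pd.DataFrame(rows))
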