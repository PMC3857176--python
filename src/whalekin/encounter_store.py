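"""Encounter database: individuals, dated group observations, sighting histories.

An *encounter* is a discrete data-collection event with one group of whales
(one or more animals in close proximity).  Individuals are identified by
photographic features (tail fluke, dorsal fin) and/or microsatellite genotype;
the linking of features to a single identity is assumed done upstream and
encoded in ``individual_id``.

Terminology used throughout the package:

* **resighted** — identified in two or more encounters (same-day resightings
  count);
* **familiar group** — an encounter whose group contains at least one
  resighted whale; groups with none are **unfamiliar**.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Individual",
    "Encounter",
    "SightingHistory",
    "EncounterStore",
    "ValidationError",
    "load_encounters",
    "write_encounters",
    "resighting_status",
    "classify_groups",
    "sighting_history",
    "ENCOUNTER_COLUMNS",
]

SEXES = ("female", "male", "unknown")
AGE_CLASSES = ("adult_or_juvenile", "calf_of_year", "yearling")

#: one row per (encounter, individual) membership
ENCOUNTER_COLUMNS = [
    "encounter_id",
    "date",
    "sighting_no",
    "location_name",
    "latitude",
    "longitude",
    "group_size_estimate",
    "individual_id",
    "sex",
    "age_class",
    "has_fluke_photo",
    "has_dorsal_photo",
    "has_genotype",
    "mother_id",
]


class ValidationError(ValueError):
    """An input table violates an encounter-store invariant."""


@dataclass(frozen=True)
class Individual:
    individual_id: str
    sex: str = "unknown"
    age_class: str = "adult_or_juvenile"
    has_fluke_photo: bool = False
    has_dorsal_photo: bool = False
    has_genotype: bool = False
    mother_id: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"individual {self.individual_id!r}: bad sex {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"individual {self.individual_id!r}: bad age_class {self.age_class!r}"
            )

    @property
    def has_id_feature(self) -> bool:
        return self.has_fluke_photo or self.has_dorsal_photo or self.has_genotype


@dataclass(frozen=True)
class Encounter:
    encounter_id: str
    date: _dt.date
    sighting_no: int
    location_name: str
    group_size_estimate: int
    member_ids: frozenset[str]
    latitude: float | None = None
    longitude: float | None = None

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValidationError(f"encounter {self.encounter_id!r}: no members")
        if self.group_size_estimate < len(self.member_ids):
            raise ValidationError(
                f"encounter {self.encounter_id!r}: group_size_estimate "
                f"{self.group_size_estimate} < {len(self.member_ids)} identified members"
            )
        if self.group_size_estimate < 1:
            raise ValidationError(f"encounter {self.encounter_id!r}: non-positive group size")


@dataclass(frozen=True)
class SightingHistory:
    individual_id: str
    encounters: tuple[Encounter, ...]
    sighting_days: tuple[_dt.date, ...]

    @property
    def n_encounters(self) -> int:
        return len(self.encounters)

    @property
    def first_seen(self) -> _dt.date:
        return self.sighting_days[0]

    @property
    def last_seen(self) -> _dt.date:
        return self.sighting_days[-1]


@dataclass
class EncounterStore:
    """Validated, indexed collection of individuals and encounters."""

    individuals: dict[str, Individual] = field(default_factory=dict)
    encounters: dict[str, Encounter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()
        self._index()

    def _validate(self) -> None:
        for enc in self.encounters.values():
            for iid in enc.member_ids:
                if iid not in self.individuals:
                    raise ValidationError(
                        f"encounter {enc.encounter_id!r} references unknown individual {iid!r}"
                    )
        for ind in self.individuals.values():
            if ind.mother_id is not None:
                mother = self.individuals.get(ind.mother_id)
                if mother is not None and mother.sex == "male":
                    raise ValidationError(
                        f"individual {ind.individual_id!r}: mother {ind.mother_id!r} is male"
                    )

    def _index(self) -> None:
        by_ind: dict[str, list[Encounter]] = {iid: [] for iid in self.individuals}
        for enc in sorted(self.encounters.values(), key=lambda e: (e.date, e.sighting_no)):
            for iid in enc.member_ids:
                by_ind[iid].append(enc)
        self._encounters_of = by_ind
        # a calf of the year appearing in any encounter must be identifiable
        for iid, encs in by_ind.items():
            ind = self.individuals[iid]
            if encs and ind.age_class == "calf_of_year" and not ind.has_id_feature:
                raise ValidationError(
                    f"calf {iid!r} appears in encounters but has no identification feature"
                )

    def encounters_of(self, individual_id: str) -> list[Encounter]:
        try:
            return list(self._encounters_of[individual_id])
        except KeyError:
            raise KeyError(f"unknown individual {individual_id!r}") from None

    def sighted_ids(self) -> list[str]:
        """Individuals that appear in at least one encounter, sorted."""
        return sorted(i for i, e in self._encounters_of.items() if e)

    @property
    def n_encounters(self) -> int:
        return len(self.encounters)

    def with_encounter(self, enc: Encounter, new_individuals: Iterable[Individual] = ()) -> "EncounterStore":
        """Return a new store with one extra encounter (used in property tests)."""
        inds = dict(self.individuals)
        for ind in new_individuals:
            inds[ind.individual_id] = ind
        encs = dict(self.encounters)
        if enc.encounter_id in encs:
            raise ValidationError(f"duplicate encounter_id {enc.encounter_id!r}")
        encs[enc.encounter_id] = enc
        return EncounterStore(inds, encs)


# ---------------------------------------------------------------------------
# CSV ingestion


_TRUTHY = {"1", "true", "yes", "t", "y"}
_FALSY = {"0", "false", "no", "f", "n", "", "nan"}


def _parse_bool(value: object, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"row {row}: cannot parse boolean {column}={value!r}")


def _parse_date(value: object, row: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValidationError(f"row {row}: malformed date {value!r}: {exc}") from None


def _opt_float(value: object) -> float | None:
    s = str(value).strip()
    if s in ("", "nan", "None"):
        return None
    return float(s)


def load_encounters(path, schema_options: Mapping | None = None) -> EncounterStore:
    """Read the one-row-per-membership encounter CSV into a validated store.

    Every input row maps to exactly one encounter membership; the same
    individual's descriptive fields must agree across rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ENCOUNTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")

    individuals: dict[str, Individual] = {}
    enc_rows: dict[str, dict] = {}
    members: dict[str, set[str]] = {}

    for pos, row in enumerate(df.itertuples(index=False), start=1):
        date = _parse_date(row.date, pos)
        eid = str(row.encounter_id)
        iid = str(row.individual_id)
        ind = Individual(
            individual_id=iid,
            sex=str(row.sex).strip() or "unknown",
            age_class=str(row.age_class).strip() or "adult_or_juvenile",
            has_fluke_photo=_parse_bool(row.has_fluke_photo, pos, "has_fluke_photo"),
            has_dorsal_photo=_parse_bool(row.has_dorsal_photo, pos, "has_dorsal_photo"),
            has_genotype=_parse_bool(row.has_genotype, pos, "has_genotype"),
            mother_id=(str(row.mother_id).strip() or None),
        )
        prev = individuals.get(iid)
        if prev is not None and prev != ind:
            raise ValidationError(f"row {pos}: conflicting descriptions of individual {iid!r}")
        individuals[iid] = ind

        meta = {
            "date": date,
            "sighting_no": int(row.sighting_no),
            "location_name": str(row.location_name),
            "latitude": _opt_float(row.latitude),
            "longitude": _opt_float(row.longitude),
            "group_size_estimate": int(row.group_size_estimate),
        }
        if eid in enc_rows:
            if enc_rows[eid] != meta:
                raise ValidationError(f"row {pos}: conflicting metadata for encounter {eid!r}")
            if iid in members[eid]:
                raise ValidationError(
                    f"row {pos}: individual {iid!r} listed twice in encounter {eid!r}"
                )
            members[eid].add(iid)
        else:
            enc_rows[eid] = meta
            members[eid] = {iid}

    encounters = {
        eid: Encounter(
            encounter_id=eid,
            member_ids=frozenset(members[eid]),
            **meta,
        )
        for eid, meta in enc_rows.items()
    }
    return EncounterStore(individuals, encounters)


def write_encounters(store: EncounterStore, path) -> pd.DataFrame:
    """Write the store back to the same one-row-per-membership schema."""
    rows = []
    for enc in sorted(store.encounters.values(), key=lambda e: (e.date, e.sighting_no, e.encounter_id)):
        for iid in sorted(enc.member_ids):
            ind = store.individuals[iid]
            rows.append(
                {
                    "encounter_id": enc.encounter_id,
                    "date": enc.date.isoformat(),
                    "sighting_no": enc.sighting_no,
                    "location_name": enc.location_name,
                    "latitude": "" if enc.latitude is None else enc.latitude,
                    "longitude": "" if enc.longitude is None else enc.longitude,
                    "group_size_estimate": enc.group_size_estimate,
                    "individual_id": iid,
                    "sex": ind.sex,
                    "age_class": ind.age_class,
                    "has_fluke_photo": ind.has_fluke_photo,
                    "has_dorsal_photo": ind.has_dorsal_photo,
                    "has_genotype": ind.has_genotype,
                    "mother_id": ind.mother_id or "",
                }
            )
    df = pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# Derived classifications


def resighting_status(store: EncounterStore) -> dict[str, str]:
    """``resighted`` iff an individual appears in >=2 encounters.

    Encounters on the same day count: a resighting is any identification
    subsequent to the first, including later the same day.
    """
    return {
        iid: ("resighted" if len(store.encounters_of(iid)) >= 2 else "non_resighted")
        for iid in store.individuals
    }


def classify_groups(store: EncounterStore) -> dict[str, str]:
    """``familiar`` iff the group contains at least one resighted whale."""
    status = resighting_status(store)
    return {
        eid: (
            "familiar"
            if any(status[m] == "resighted" for m in enc.member_ids)
            else "unfamiliar"
        )
        for eid, enc in store.encounters.items()
    }


def sighting_history(store: EncounterStore, individual_id: str) -> SightingHistory:
    """Chronological encounters and distinct sighting days for one whale."""
    if individual_id not in store.individuals:
        raise KeyError(f"unknown individual {individual_id!r}")
    encs = store.encounters_of(individual_id)
    if not encs:
        raise KeyError(f"individual {individual_id!r} was never encountered")
    days = sorted({e.date for e in encs})
    return SightingHistory(individual_id, tuple(encs), tuple(days))
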