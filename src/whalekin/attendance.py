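"""Seasonal attendance statistics: occurrence, occupancy, sex ratios, group sizes.

The analysis year is a *seasonal cycle* running from 1 April to 31 March of
the following calendar year, offset to keep over-summering whales inside a
single unit.  Within a cycle,

* **occurrence** is the number of distinct days a whale was sighted, and
* **occupancy** is the number of days between its first and last sighting
  dates (counted from the day after the first sighting, so consecutive-day
  sightings give an occupancy of 1); it is defined only for whales seen on
  at least two days.

The *operational sex ratio* (OSR) counts (individual, day) identification
events of known-sex, non-calf whales, pooled by month-based seasonal
grouping across years, and is expressed as 1 female : x males.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .encounter_store import EncounterStore, classify_groups, resighting_status

__all__ = [
    "SeasonalCycle",
    "AttendanceRecord",
    "SEASONAL_GROUPING_BY_MONTH",
    "SEASONAL_GROUPINGS",
    "seasonal_grouping",
    "cycles_in_store",
    "occurrence_occupancy",
    "mean_occurrence",
    "osr_table",
    "sex_ratio_test",
    "sex_ratio_2x2_test",
    "group_size_stats",
    "GroupSizeReport",
    "pair_sex_composition",
    "expected_pair_composition",
    "occupancy_by_sex_test",
]


@dataclass(frozen=True, order=True)
class SeasonalCycle:
    """12-month analysis window from 1 April of ``start_year`` to 31 March."""

    start_year: int

    @property
    def start(self) -> _dt.date:
        return _dt.date(self.start_year, 4, 1)

    @property
    def end(self) -> _dt.date:
        return _dt.date(self.start_year + 1, 3, 31)

    @property
    def label(self) -> str:
        return f"{self.start_year}/{(self.start_year + 1) % 100:02d}"

    @classmethod
    def of(cls, date: _dt.date) -> "SeasonalCycle":
        return cls(date.year if date.month >= 4 else date.year - 1)

    def contains(self, date: _dt.date) -> bool:
        return self.start <= date <= self.end


@dataclass(frozen=True)
class AttendanceRecord:
    individual_id: str
    cycle: SeasonalCycle
    occurrence: int
    occupancy: int | None  # None when seen on fewer than two distinct days


#: month -> seasonal grouping; March and April belong to no grouping.
SEASONAL_GROUPING_BY_MONTH: dict[int, str | None] = {
    1: "mid_late_summer",
    2: "mid_late_summer",
    3: None,
    4: None,
    5: "late_autumn_to_mid_winter",
    6: "late_autumn_to_mid_winter",
    7: "late_autumn_to_mid_winter",
    8: "late_winter",
    9: "early_spring",
    10: "mid_spring",
    11: "late_spring",
    12: "early_summer",
}

#: groupings in seasonal order (May through February)
SEASONAL_GROUPINGS = [
    "late_autumn_to_mid_winter",
    "late_winter",
    "early_spring",
    "mid_spring",
    "late_spring",
    "early_summer",
    "mid_late_summer",
]


def seasonal_grouping(date: _dt.date) -> str | None:
    return SEASONAL_GROUPING_BY_MONTH[date.month]


def cycles_in_store(store: EncounterStore) -> list[SeasonalCycle]:
    return sorted({SeasonalCycle.of(e.date) for e in store.encounters.values()})


def occurrence_occupancy(store: EncounterStore, cycle: SeasonalCycle) -> list[AttendanceRecord]:
    """One record per individual sighted within the cycle."""
    days: dict[str, set[_dt.date]] = {}
    for enc in store.encounters.values():
        if cycle.contains(enc.date):
            for iid in enc.member_ids:
                days.setdefault(iid, set()).add(enc.date)
    records = []
    for iid in sorted(days):
        d = sorted(days[iid])
        occupancy = (d[-1] - d[0]).days if len(d) >= 2 else None
        records.append(AttendanceRecord(iid, cycle, len(d), occupancy))
    return records


def mean_occurrence(records: Iterable[AttendanceRecord] | Mapping[int, int]) -> float:
    """Frequency-weighted mean occurrence.

    Accepts either attendance records or a ``{occurrence: count}`` table.
    """
    if isinstance(records, Mapping):
        freqs = dict(records)
    else:
        freqs = Counter(r.occurrence for r in records)
    total = sum(freqs.values())
    if total == 0:
        raise ValueError("empty occurrence distribution")
    return sum(v * n for v, n in freqs.items()) / total


# ---------------------------------------------------------------------------
# Sex composition


def sex_ratio_test(f_count: int, m_count: int, yates: bool = False) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of a sex ratio against parity (1:1).

    Returns ``(chi2, p)``.  Yates continuity correction is applied only when
    requested (conventionally for 2x2 comparisons, not this goodness-of-fit).
    """
    if f_count < 0 or m_count < 0:
        raise ValueError("counts must be nonnegative")
    n = f_count + m_count
    if n == 0:
        raise ValueError("both counts zero")
    e = n / 2.0
    c = 0.5 if yates else 0.0
    dev = max(abs(f_count - e) - c, 0.0)
    chi2 = 2 * dev**2 / e
    return chi2, float(stats.chi2.sf(chi2, df=1))


def sex_ratio_2x2_test(
    f_a: int, m_a: int, f_b: int, m_b: int, yates: bool = True
) -> tuple[float, float]:
    """2x2 contingency chi-square comparing two sex ratios (Yates-corrected).

    Used to compare resighted vs non-resighted sample sex ratios.
    """
    table = np.array([[f_a, m_a], [f_b, m_b]])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def osr_table(store: EncounterStore, exclude_calves: bool = True) -> pd.DataFrame:
    """Operational sex ratio per seasonal grouping and resighting class.

    Counting unit: distinct (individual, day) identification events of
    known-sex individuals, pooled across years within each month-based
    grouping.  Calves of the year are excluded by default; March and April
    events fall in no grouping and are dropped (their count is reported in
    the ``march_april_excluded`` DataFrame attribute).

    Returns a tidy frame with columns grouping, status, females, males,
    ratio_m_per_f, chi2, p; status is resighted / non_resighted / all.
    """
    status = resighting_status(store)
    events: set[tuple[str, _dt.date]] = set()
    for enc in store.encounters.values():
        for iid in enc.member_ids:
            events.add((iid, enc.date))

    dropped = 0
    counts: Counter[tuple[str, str, str]] = Counter()
    for iid, date in events:
        ind = store.individuals[iid]
        if ind.sex == "unknown":
            continue
        if exclude_calves and ind.age_class == "calf_of_year":
            continue
        grouping = seasonal_grouping(date)
        if grouping is None:
            dropped += 1
            continue
        counts[(grouping, status[iid], ind.sex)] += 1

    rows = []
    for grouping in SEASONAL_GROUPINGS:
        for st in ("resighted", "non_resighted", "all"):
            if st == "all":
                f = counts[(grouping, "resighted", "female")] + counts[(grouping, "non_resighted", "female")]
                m = counts[(grouping, "resighted", "male")] + counts[(grouping, "non_resighted", "male")]
            else:
                f = counts[(grouping, st, "female")]
                m = counts[(grouping, st, "male")]
            if f + m > 0:
                chi2, p = sex_ratio_test(f, m)
            else:
                chi2, p = np.nan, np.nan
            rows.append(
                {
                    "grouping": grouping,
                    "status": st,
                    "females": f,
                    "males": m,
                    "ratio_m_per_f": (m / f) if f > 0 else np.nan,
                    "chi2": chi2,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["march_april_excluded"] = dropped
    return out


# ---------------------------------------------------------------------------
# Group sizes


@dataclass
class GroupSizeReport:
    """Familiar/unfamiliar group-size comparison under four filters."""

    table: pd.DataFrame  # per (variant, class): n, mean, se, min, max, prop_singles
    tests: dict[str, tuple[float, int, float]]  # variant -> (t, df, p)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [self.table.to_string(index=False), ""]
        for variant, (t, df, p) in self.tests.items():
            lines.append(f"{variant}: t = {t:.3f}, df = {df}, P = {p:.4g}")
        return "\n".join(lines)


_VARIANTS = ("all", "size_gt1", "no_outlier", "size_gt1_no_outlier")


def _filter_sizes(sizes: list[int], variant: str) -> list[int]:
    out = list(sizes)
    if "no_outlier" in variant and out:
        out.remove(max(out))  # drop the single largest group in the class
    if "gt1" in variant:
        out = [s for s in out if s > 1]
    return out


def group_size_stats(store: EncounterStore) -> GroupSizeReport:
    """Mean/SE/range of estimated group size for familiar vs unfamiliar groups.

    Four comparisons are reported: all groups; groups larger than 1; with the
    single largest group per class removed; and both filters combined.  Each
    comparison carries an unpaired two-sample t-test.
    """
    classes = classify_groups(store)
    sizes: dict[str, list[int]] = {"familiar": [], "unfamiliar": []}
    for eid, enc in store.encounters.items():
        sizes[classes[eid]].append(enc.group_size_estimate)

    rows = []
    tests: dict[str, tuple[float, int, float]] = {}
    for variant in _VARIANTS:
        samples = {}
        for cls in ("familiar", "unfamiliar"):
            s = _filter_sizes(sizes[cls], variant)
            samples[cls] = s
            arr = np.asarray(s, dtype=float)
            rows.append(
                {
                    "variant": variant,
                    "class": cls,
                    "n": len(s),
                    "mean": arr.mean() if len(s) else np.nan,
                    "se": arr.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan,
                    "min": int(arr.min()) if len(s) else np.nan,
                    "max": int(arr.max()) if len(s) else np.nan,
                    "prop_singles": float(np.mean(arr == 1)) if len(s) else np.nan,
                }
            )
        a, b = samples["familiar"], samples["unfamiliar"]
        if len(a) >= 2 and len(b) >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            if np.isnan(t) and np.mean(a) == np.mean(b):
                t, p = 0.0, 1.0  # identical constant samples
            tests[variant] = (float(t), len(a) + len(b) - 2, float(p))
        else:
            warnings.warn(f"group_size_stats: t-test omitted for {variant!r} (class too small)")
    return GroupSizeReport(pd.DataFrame(rows), tests)


# ---------------------------------------------------------------------------
# Pair sex composition


def expected_pair_composition(n_pairs: int, m_per_f: float) -> tuple[float, float, float]:
    """Binomial expectation of (mixed, female-female, male-male) pair counts.

    ``m_per_f`` is the sex ratio expressed as males per female (the x in
    1F : xM); the implied female proportion is p = 1/(1+x).
    """
    p = 1.0 / (1.0 + m_per_f)
    return (n_pairs * 2 * p * (1 - p), n_pairs * p * p, n_pairs * (1 - p) * (1 - p))


def pair_sex_composition(
    store: EncounterStore, m_per_f: float | None = None, exclude_calves: bool = True
) -> pd.DataFrame:
    """Observed vs expected sex composition of two-whale groups.

    Considers encounters whose identified group is exactly a dyad with both
    members of known sex (calves excluded by default), de-duplicating repeats
    of the same pair on the same day.  Expected counts assume random pairing
    of sexes at the supplied ratio (males per female); when omitted, the
    ratio of sexed non-calf individuals in the store is used.
    """
    classes = classify_groups(store)
    seen: set[tuple[str, str, _dt.date]] = set()
    counts: Counter[tuple[str, str]] = Counter()
    for eid, enc in store.encounters.items():
        if len(enc.member_ids) != 2:
            continue
        a, b = sorted(enc.member_ids)
        ia, ib = store.individuals[a], store.individuals[b]
        if "unknown" in (ia.sex, ib.sex):
            continue
        if exclude_calves and "calf_of_year" in (ia.age_class, ib.age_class):
            continue
        key = (a, b, enc.date)
        if key in seen:  # same pair, same day
            continue
        seen.add(key)
        comp = "mixed" if ia.sex != ib.sex else ("female_female" if ia.sex == "female" else "male_male")
        counts[(classes[eid], comp)] += 1

    if m_per_f is None:
        sexes = [
            i.sex
            for i in store.individuals.values()
            if i.sex != "unknown" and not (exclude_calves and i.age_class == "calf_of_year")
        ]
        n_f = sexes.count("female")
        n_m = sexes.count("male")
        m_per_f = (n_m / n_f) if n_f else np.nan

    rows = []
    for cls in ("familiar", "unfamiliar"):
        n = sum(counts[(cls, c)] for c in ("mixed", "female_female", "male_male"))
        exp = expected_pair_composition(n, m_per_f) if n and np.isfinite(m_per_f) else (np.nan,) * 3
        for comp, e in zip(("mixed", "female_female", "male_male"), exp):
            rows.append(
                {
                    "class": cls,
                    "composition": comp,
                    "observed": counts[(cls, comp)],
                    "expected": e,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["m_per_f"] = m_per_f
    return out


# ---------------------------------------------------------------------------
# Convenience


def occupancy_by_sex_test(store: EncounterStore, exclude_calves: bool = True):
    """Kruskal-Wallis comparison of within-cycle occupancy across sexes.

    Thin convenience wrapper used by the report command; pools attendance
    records over all cycles, one occupancy value per (individual, cycle).
    """
    groups: dict[str, list[int]] = {"female": [], "male": [], "unknown": []}
    for cycle in cycles_in_store(store):
        for rec in occurrence_occupancy(store, cycle):
            if rec.occupancy is None:
                continue
            ind = store.individuals[rec.individual_id]
            if exclude_calves and ind.age_class == "calf_of_year":
                continue
            groups[ind.sex].append(rec.occupancy)
    samples = [v for v in groups.values() if v]
    if len(samples) < 2:
        return np.nan, np.nan, groups
    h, p = stats.kruskal(*samples)
    return float(h), float(p), groups
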