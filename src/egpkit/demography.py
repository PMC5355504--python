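"""Census parsing, male group-membership intervals and breeding-group composition.

The demographic backbone of the analysis: individual life-history records,
male residence intervals derived from near-daily census sightings via the
30/60-day confirmation rules, and the per-season group composition measures
(breeding group size and sex ratio).

Females are philopatric and are treated as lifelong members of their natal
group; only male residence is derived from sightings.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._dates import as_date, from_ordinal, ordinal, to_ordinals

MALE = "male"
FEMALE = "female"

#: sighting contexts that trigger the longer residence-confirmation rule
NONROUTINE_CONTEXTS = frozenset({"prospecting", "bachelor", "solitary"})
VALID_CONTEXTS = frozenset({"routine"}) | NONROUTINE_CONTEXTS

_OPEN = np.iinfo(np.int64).max // 2  # sentinel ordinal for open-ended intervals


@dataclass(frozen=True)
class Individual:
    """One animal in the census database."""

    id: str
    sex: str
    birth_date: datetime.date
    death_date: Optional[datetime.date] = None
    natal_group: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "birth_date", as_date(self.birth_date))
        if self.death_date is not None:
            object.__setattr__(self, "death_date", as_date(self.death_date))
            if self.death_date < self.birth_date:
                raise ValueError(
                    f"{self.id}: death_date {self.death_date} precedes birth_date"
                )
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"{self.id}: sex must be 'male' or 'female'")

    def age_days(self, date) -> int:
        """Age in completed days on ``date``."""
        return ordinal(date) - self.birth_date.toordinal()

    def alive_on(self, date) -> bool:
        o = ordinal(date)
        if o < self.birth_date.toordinal():
            return False
        return self.death_date is None or o <= self.death_date.toordinal()


@dataclass(frozen=True)
class SightingEvent:
    """One census record of a male in a group on a day."""

    individual_id: str
    date: datetime.date
    group: str
    context: str = "routine"

    def __post_init__(self):
        object.__setattr__(self, "date", as_date(self.date))
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"unknown sighting context {self.context!r}")


@dataclass(frozen=True)
class MembershipInterval:
    """A male's confirmed residence in one group over a closed date interval.

    ``end_date is None`` means the interval is open (still resident at the
    end of observation).
    """

    individual_id: str
    group: str
    start_date: datetime.date
    end_date: Optional[datetime.date] = None

    def __post_init__(self):
        object.__setattr__(self, "start_date", as_date(self.start_date))
        if self.end_date is not None:
            object.__setattr__(self, "end_date", as_date(self.end_date))
            if self.end_date < self.start_date:
                raise ValueError(
                    f"{self.individual_id}: interval end precedes start"
                )

    def covers(self, date) -> bool:
        o = ordinal(date)
        if o < self.start_date.toordinal():
            return False
        return self.end_date is None or o <= self.end_date.toordinal()


@dataclass(frozen=True)
class MembershipRules:
    """Residence-confirmation rules for male group transfers.

    A candidate transfer is confirmed once the male's sighted group has
    remained constant for ``routine_confirm_days``; if any sighting within
    the first ``routine_confirm_days`` of the candidate period is
    non-routine (prospecting / bachelor-group / solitary), confirmation
    instead requires ``prospecting_confirm_days`` of constant residence.
    ``max_gap_days`` bounds the tolerated census gap inside a confirmation
    period (the census is near-daily).
    """

    routine_confirm_days: int = 30
    prospecting_confirm_days: int = 60
    maturity_age_days: int = 1250
    max_gap_days: int = 7

    def __post_init__(self):
        if min(self.routine_confirm_days, self.prospecting_confirm_days,
               self.maturity_age_days, self.max_gap_days) <= 0:
            raise ValueError("all rule constants must be positive")
        if self.prospecting_confirm_days < self.routine_confirm_days:
            raise ValueError("prospecting_confirm_days must be >= routine_confirm_days")


@dataclass(frozen=True)
class SeasonCalendar:
    """Mating-season window for one group and birth cohort."""

    group: str
    cohort_year: int
    mating_season_onset: datetime.date
    mating_season_end: datetime.date

    def __post_init__(self):
        object.__setattr__(self, "mating_season_onset", as_date(self.mating_season_onset))
        object.__setattr__(self, "mating_season_end", as_date(self.mating_season_end))
        if not self.mating_season_onset < self.mating_season_end:
            raise ValueError("mating season onset must precede its end")

    @property
    def n_days(self) -> int:
        return (self.mating_season_end - self.mating_season_onset).days + 1


def _sightings_to_arrays(sightings):
    """Normalize sightings to (ids, ordinals, groups, nonroutine) arrays."""
    if isinstance(sightings, pd.DataFrame):
        ids = sightings["id"].to_numpy()
        dates = to_ordinals(sightings["date"].to_numpy())
        groups = sightings["group"].to_numpy()
        ctx = sightings["context"].to_numpy() if "context" in sightings else None
    else:
        events = list(sightings)
        ids = np.array([e.individual_id for e in events], dtype=object)
        dates = np.array([e.date.toordinal() for e in events], dtype=np.int64)
        groups = np.array([e.group for e in events], dtype=object)
        ctx = np.array([e.context for e in events], dtype=object)
    if ctx is None:
        nonroutine = np.zeros(len(ids), dtype=bool)
    else:
        bad = ~np.isin(ctx, list(VALID_CONTEXTS))
        if bad.any():
            raise ValueError(f"unknown sighting context {ctx[bad][0]!r}")
        nonroutine = np.isin(ctx, list(NONROUTINE_CONTEXTS))
    return ids, dates, groups, nonroutine


def build_membership_intervals(
    sightings,
    rules: MembershipRules = MembershipRules(),
    individuals: Optional[Iterable[Individual]] = None,
) -> list[MembershipInterval]:
    """Derive confirmed male residence intervals from census sightings.

    Sightings must be sorted by (individual, date).  A transfer to a new
    group is confirmed once residence there has remained constant for the
    required number of days (30, or 60 if any non-routine sighting occurred
    within the first 30 days), with no census gap exceeding
    ``rules.max_gap_days`` inside the confirmation span.  The confirmed
    interval starts on the first day the male was seen in the new group; the
    previous interval ends the day before.  A death closes the open interval.

    Parameters
    ----------
    sightings
        Sequence of :class:`SightingEvent` or a DataFrame with columns
        ``id, date, group[, context]``, sorted by (individual, date).
    rules
        Residence-confirmation rules.
    individuals
        Optional census records; used to close intervals at death and to
        reject sightings of unknown individuals.
    """
    ids, dates, groups, nonroutine = _sightings_to_arrays(sightings)
    if len(ids) == 0:
        return []

    deaths: dict[str, int] = {}
    known: Optional[set] = None
    if individuals is not None:
        inds = list(individuals)
        known = {i.id for i in inds}
        deaths = {
            i.id: i.death_date.toordinal() for i in inds if i.death_date is not None
        }

    # locate contiguous per-individual blocks and check sortedness
    change = np.flatnonzero(ids[1:] != ids[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(ids)]))
    seen: set = set()

    intervals: list[MembershipInterval] = []
    for blk_start, blk_stop in zip(starts, stops):
        mid = ids[blk_start]
        if mid in seen:
            raise ValueError(
                f"sightings not sorted by (individual, date): {mid!r} appears twice"
            )
        seen.add(mid)
        if known is not None and mid not in known:
            raise ValueError(f"sighting for unknown individual {mid!r}")
        d = dates[blk_start:blk_stop]
        if np.any(np.diff(d) < 0):
            raise ValueError(f"sightings for {mid!r} are not sorted by date")
        g = groups[blk_start:blk_stop]
        nr = nonroutine[blk_start:blk_stop]
        intervals.extend(
            _intervals_for_male(mid, d, g, nr, rules, deaths.get(mid))
        )
    intervals.sort(key=lambda iv: (iv.individual_id, iv.start_date))
    return intervals


def _intervals_for_male(mid, d, g, nr, rules, death_ord):
    out = []
    conf_group = None  # confirmed current group
    conf_start = None
    pend_group = None  # candidate transfer under observation
    pend_start = None
    pend_last = None
    pend_flag = False

    def close_confirmed(end_ord):
        out.append(
            MembershipInterval(mid, conf_group, from_ordinal(conf_start),
                               from_ordinal(end_ord))
        )

    for i in range(len(d)):
        day, grp, flag = int(d[i]), g[i], bool(nr[i])
        if pend_group is not None:
            if grp == pend_group:
                if day - pend_last > rules.max_gap_days:
                    # census gap too large: restart the candidate period
                    pend_start, pend_flag = day, flag
                else:
                    if flag and day - pend_start < rules.routine_confirm_days:
                        pend_flag = True
                pend_last = day
                need = (rules.prospecting_confirm_days if pend_flag
                        else rules.routine_confirm_days)
                if day - pend_start + 1 >= need:
                    if conf_group is not None:
                        close_confirmed(pend_start - 1)
                    conf_group, conf_start = pend_group, pend_start
                    pend_group = None
                continue
            if grp == conf_group:
                pend_group = None  # reverted to the resident group
                continue
            pend_group, pend_start, pend_last, pend_flag = grp, day, day, flag
            continue
        if conf_group is None or grp != conf_group:
            pend_group, pend_start, pend_last, pend_flag = grp, day, day, flag

    if conf_group is not None:
        if pend_group is not None:
            # left the group but the transfer was never confirmed: the
            # confirmed residence ends the day before he was first seen away
            end = pend_start - 1
            if death_ord is not None:
                end = min(end, death_ord)
            close_confirmed(end)
        elif death_ord is not None:
            close_confirmed(death_ord)
        else:
            out.append(
                MembershipInterval(mid, conf_group, from_ordinal(conf_start), None)
            )
    return out


def validate_intervals(intervals: Sequence[MembershipInterval]) -> None:
    """Raise if any individual has overlapping intervals (one group per day)."""
    by_ind: dict[str, list[MembershipInterval]] = {}
    for iv in intervals:
        by_ind.setdefault(iv.individual_id, []).append(iv)
    for mid, ivs in by_ind.items():
        ivs = sorted(ivs, key=lambda iv: iv.start_date)
        for a, b in zip(ivs, ivs[1:]):
            a_end = a.end_date.toordinal() if a.end_date else _OPEN
            if b.start_date.toordinal() <= a_end:
                raise ValueError(f"{mid}: overlapping membership intervals")


class MembershipIndex:
    """Fast membership queries over individuals + male residence intervals.

    Males are members while a confirmed interval covers the date; females
    are lifelong members of their natal group (philopatry) while alive.
    """

    def __init__(self, individuals: Iterable[Individual],
                 intervals: Sequence[MembershipInterval]):
        self.individuals = {i.id: i for i in individuals}
        self.intervals = list(intervals)
        validate_intervals(self.intervals)

        by_group: dict[str, list] = {}
        by_ind: dict[str, list] = {}
        for iv in self.intervals:
            by_group.setdefault(iv.group, []).append(iv)
            by_ind.setdefault(iv.individual_id, []).append(iv)
        self._by_ind = {
            k: sorted(v, key=lambda iv: iv.start_date) for k, v in by_ind.items()
        }

        self._grp: dict[str, dict] = {}
        groups = set(by_group)
        for i in self.individuals.values():
            if i.natal_group is not None:
                groups.add(i.natal_group)
        for grp in groups:
            ivs = by_group.get(grp, [])
            male_ids = np.array([iv.individual_id for iv in ivs], dtype=object)
            start = np.array([iv.start_date.toordinal() for iv in ivs], dtype=np.int64)
            end = np.array(
                [iv.end_date.toordinal() if iv.end_date else _OPEN for iv in ivs],
                dtype=np.int64,
            )
            m_birth = np.array(
                [self._birth_ord(i) for i in male_ids], dtype=np.int64
            )
            fem = [
                i for i in self.individuals.values()
                if i.sex == FEMALE and i.natal_group == grp
            ]
            f_ids = np.array([i.id for i in fem], dtype=object)
            f_birth = np.array([i.birth_date.toordinal() for i in fem], dtype=np.int64)
            f_death = np.array(
                [i.death_date.toordinal() if i.death_date else _OPEN for i in fem],
                dtype=np.int64,
            )
            self._grp[grp] = dict(
                male_ids=male_ids, start=start, end=end, m_birth=m_birth,
                f_ids=f_ids, f_birth=f_birth, f_death=f_death,
            )

    def _birth_ord(self, mid) -> int:
        ind = self.individuals.get(mid)
        return ind.birth_date.toordinal() if ind is not None else -_OPEN

    # -- scalar queries -------------------------------------------------
    def members_on_date(self, group: str, date) -> set:
        o = ordinal(date)
        rec = self._grp.get(group)
        if rec is None:
            return set()
        males = rec["male_ids"][(rec["start"] <= o) & (o <= rec["end"])]
        fems = rec["f_ids"][(rec["f_birth"] <= o) & (o <= rec["f_death"])]
        return set(males) | set(fems)

    def is_member(self, individual_id: str, group: str, date) -> bool:
        o = ordinal(date)
        ind = self.individuals.get(individual_id)
        if ind is not None and ind.sex == FEMALE:
            return (ind.natal_group == group and ind.alive_on(date))
        for iv in self._by_ind.get(individual_id, []):
            if iv.group == group and iv.covers(date):
                return True
        return False

    def tenure_on_date(self, individual_id: str, date) -> int:
        o = ordinal(date)
        for iv in self._by_ind.get(individual_id, []):
            if iv.covers(date):
                return o - iv.start_date.toordinal() + 1
        return 0

    def membership_overlap_days(self, individual_id: str, group: str,
                                start, end) -> int:
        """Days within [start, end] on which the individual was a member."""
        s, e = ordinal(start), ordinal(end)
        ind = self.individuals.get(individual_id)
        if ind is not None and ind.sex == FEMALE:
            if ind.natal_group != group:
                return 0
            b = ind.birth_date.toordinal()
            d = ind.death_date.toordinal() if ind.death_date else _OPEN
            return max(0, min(e, d) - max(s, b) + 1)
        total = 0
        for iv in self._by_ind.get(individual_id, []):
            if iv.group != group:
                continue
            a = iv.start_date.toordinal()
            b = iv.end_date.toordinal() if iv.end_date else _OPEN
            total += max(0, min(e, b) - max(s, a) + 1)
        return total

    # -- vectorized daily tabulations -----------------------------------
    def daily_mature_counts(self, group: str, day_ordinals: np.ndarray,
                            maturity_age_days: int = 1250):
        """(n_females, n_males) members older than ``maturity_age_days``
        on each day, as integer arrays."""
        days = np.asarray(day_ordinals, dtype=np.int64)
        rec = self._grp.get(group)
        if rec is None:
            z = np.zeros(len(days), dtype=np.int64)
            return z, z.copy()
        d = days[None, :]
        m_present = (rec["start"][:, None] <= d) & (d <= rec["end"][:, None])
        m_mature = (d - rec["m_birth"][:, None]) > maturity_age_days
        n_m = (m_present & m_mature).sum(axis=0)
        f_present = (rec["f_birth"][:, None] <= d) & (d <= rec["f_death"][:, None])
        f_mature = (d - rec["f_birth"][:, None]) > maturity_age_days
        n_f = (f_present & f_mature).sum(axis=0)
        return n_f, n_m

    def male_presence_matrix(self, group: str, day_ordinals: np.ndarray):
        """Per-interval presence and tenure over a range of days.

        Returns ``(ids, present, tenure)`` where ``present`` is a boolean
        (n_intervals, n_days) matrix and ``tenure`` holds the inclusive
        residence day count (start day = 1) where present, else 0.
        """
        days = np.asarray(day_ordinals, dtype=np.int64)
        rec = self._grp.get(group)
        if rec is None or len(rec["male_ids"]) == 0:
            return (np.empty(0, dtype=object),
                    np.zeros((0, len(days)), dtype=bool),
                    np.zeros((0, len(days)), dtype=np.int64))
        d = days[None, :]
        present = (rec["start"][:, None] <= d) & (d <= rec["end"][:, None])
        tenure = np.where(present, d - rec["start"][:, None] + 1, 0)
        return rec["male_ids"], present, tenure


# -- module-level convenience wrappers ---------------------------------

def members_on_date(intervals, group, date, individuals=()) -> set:
    """Members of ``group`` on ``date`` (males via intervals, females via
    natal philopatry)."""
    return MembershipIndex(individuals, intervals).members_on_date(group, date)


def tenure_on_date(intervals, individual_id, date) -> int:
    """Inclusive residence day count (start day = tenure 1); 0 if not a member."""
    o = ordinal(date)
    for iv in intervals:
        if iv.individual_id == individual_id and iv.covers(date):
            return o - iv.start_date.toordinal() + 1
    return 0


def breeding_group_composition(group, season: SeasonCalendar, individuals,
                               intervals, maturity_age_days: int = 1250):
    """(n_females, n_males) older than ``maturity_age_days`` at mating-season
    onset; group size is their sum.  The age criterion is strict (>)."""
    index = (intervals if isinstance(intervals, MembershipIndex)
             else MembershipIndex(individuals, intervals))
    onset = np.array([season.mating_season_onset.toordinal()], dtype=np.int64)
    n_f, n_m = index.daily_mature_counts(group, onset, maturity_age_days)
    return int(n_f[0]), int(n_m[0])


def sex_ratio(group, season: SeasonCalendar, individuals, intervals,
              method: str = "daily", maturity_age_days: int = 1250) -> float:
    """Breeding-group sex ratio: average adult females / average adult males.

    ``method="daily"`` (default) averages daily mature member counts over
    every day of the mating season; ``method="onset"`` uses a single census
    at season onset.  Raises if the male average is zero.
    """
    index = (intervals if isinstance(intervals, MembershipIndex)
             else MembershipIndex(individuals, intervals))
    o0 = season.mating_season_onset.toordinal()
    o1 = season.mating_season_end.toordinal()
    if method == "daily":
        days = np.arange(o0, o1 + 1)
    elif method == "onset":
        days = np.array([o0], dtype=np.int64)
    else:
        raise ValueError(f"unknown sex-ratio method {method!r}")
    n_f, n_m = index.daily_mature_counts(group, days, maturity_age_days)
    mean_m = n_m.mean()
    if mean_m == 0:
        raise ValueError(f"{group}: no adult males during the season; "
                         "sex ratio undefined")
    return float(n_f.mean() / mean_m)


def filter_offspring_cohort(
    births: pd.DataFrame,
    individuals: Mapping[str, Individual] | Iterable[Individual],
    genotyped: set,
    persistent_groups: Optional[set] = None,
    min_survival_days: int = 365,
):
    """Apply the offspring-inclusion criteria and log every exclusion.

    Removes (in order of reason precedence): infants of groups not present
    for the whole study, ungenotyped infants, infants removed together with
    their mother before age one, and infants that died within their first
    year.  Returns ``(retained, exclusions)`` DataFrames; the exclusion log
    has columns ``offspring, reason``.
    """
    if not isinstance(individuals, Mapping):
        individuals = {i.id: i for i in individuals}
    reasons = []
    for row in births.itertuples(index=False):
        oid = row.offspring
        reason = None
        if persistent_groups is not None and row.natal_group not in persistent_groups:
            reason = "group_not_persistent"
        elif oid not in genotyped:
            reason = "ungenotyped"
        else:
            ind = individuals.get(oid)
            if ind is not None and ind.death_date is not None:
                lived = (ind.death_date - ind.birth_date).days
                if lived < min_survival_days:
                    mother = individuals.get(row.mother)
                    if (mother is not None and mother.death_date is not None
                            and mother.death_date == ind.death_date):
                        reason = "removed_with_mother<1y"
                    else:
                        reason = "died<1y"
        reasons.append(reason)
    mask = np.array([r is None for r in reasons])
    retained = births.loc[mask].reset_index(drop=True)
    exclusions = pd.DataFrame({
        "offspring": births.loc[~mask, "offspring"].to_numpy(),
        "reason": [r for r in reasons if r is not None],
    })
    assert len(retained) + len(exclusions) == len(births)
    return retained, exclusions
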