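"""Membership intervals, group composition and the offspring filter."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from egpkit.demography import (Individual, MembershipIndex, MembershipRules,
                               SeasonCalendar, SightingEvent,
                               breeding_group_composition,
                               build_membership_intervals,
                               filter_offspring_cohort, members_on_date,
                               sex_ratio, tenure_on_date, validate_intervals)

import _oracles

D0 = dt.date(2005, 1, 1)


def day(k: int) -> dt.date:
    return D0 + dt.timedelta(days=k)


def sightings(mid, spec):
    """spec: iterable of (day_index, group) or (day_index, group, context)."""
    out = []
    for item in spec:
        k, g, *ctx = item
        out.append(SightingEvent(mid, day(k), g,
                                 ctx[0] if ctx else "routine"))
    return out


class TestResidenceConfirmation:
    def test_interval_confirmed_after_30_days_constant_routine(self):
        """A male seen daily in one group for 40 days is resident from the
        first sighting day on."""
        iv = build_membership_intervals(
            sightings("m1", [(k, "G") for k in range(41)]))
        assert len(iv) == 1
        assert iv[0].group == "G"
        assert iv[0].start_date == day(0)
        assert iv[0].end_date is None

    def test_short_visit_never_becomes_residence(self):
        """20 days away then back home: no interval for the visited group."""
        home = [(k, "H") for k in range(-120, 0)]
        away = [(k, "G") for k in range(0, 21)]
        back = [(k, "H") for k in range(21, 80)]
        iv = build_membership_intervals(sightings("m1", home + away + back))
        assert {v.group for v in iv} == {"H"}
        assert len(iv) == 1  # the visit never interrupts residence

    def test_prospecting_extends_confirmation_to_60_days(self):
        """A prospecting sighting inside the first 30 days defers
        assignment until 60 days of constant residence; the immigration
        date stays the first sighting day."""
        home = [(k, "H") for k in range(-120, 0)]
        new = [(k, "G", "prospecting" if k == 10 else "routine")
               for k in range(0, 66)]
        iv = build_membership_intervals(sightings("m1", home + new))
        by_group = {v.group: v for v in iv}
        assert by_group["G"].start_date == day(0)
        assert by_group["H"].end_date == day(-1)
        # truncating at 45 days of constancy must NOT confirm the transfer
        iv_short = build_membership_intervals(
            sightings("m1", home + new[:46]))
        assert {v.group for v in iv_short} == {"H"}

    def test_previous_interval_ends_day_before_transfer(self):
        first = [(k, "A") for k in range(0, 100)]
        second = [(k, "B") for k in range(100, 180)]
        iv = build_membership_intervals(sightings("m1", first + second))
        a = next(v for v in iv if v.group == "A")
        b = next(v for v in iv if v.group == "B")
        assert a.end_date == day(99)
        assert b.start_date == day(100)

    def test_death_closes_open_interval(self):
        ind = Individual("m1", "male", day(-4000), day(50), "A")
        iv = build_membership_intervals(
            sightings("m1", [(k, "A") for k in range(0, 49, 3)]),
            individuals=[ind])
        assert iv[0].end_date == day(50)

    def test_unsorted_or_unknown_input_rejected(self):
        bad = sightings("m1", [(5, "A"), (1, "A")])
        with pytest.raises(ValueError, match="sorted"):
            build_membership_intervals(bad)
        with pytest.raises(ValueError, match="unknown"):
            build_membership_intervals(
                sightings("ghost", [(0, "A")]),
                individuals=[Individual("m1", "male", day(-4000))])

    def test_duplicated_sightings_are_harmless(self):
        base = sightings("m1", [(k, "G") for k in range(41)])
        doubled = sorted(base + base, key=lambda s: s.date)
        assert build_membership_intervals(base) == \
            build_membership_intervals(doubled)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 300),
                              st.sampled_from(["A", "B", "C"])),
                    min_size=1, max_size=60))
    def test_one_group_per_day_exclusivity(self, raw):
        """However messy the sighting history, derived intervals never let a
        male belong to two groups on the same day."""
        raw = sorted(set(raw))
        iv = build_membership_intervals(
            sightings("m1", [(k, g) for k, g in raw]))
        validate_intervals(iv)


class TestMembershipQueries:
    def _intervals(self):
        return build_membership_intervals(
            sightings("m1", [(k, "G") for k in range(0, 100, 2)]))

    def test_closed_interval_boundaries(self):
        home = [(k, "A") for k in range(-200, 0)]
        away = [(k, "B") for k in range(0, 60)]
        iv = build_membership_intervals(sightings("m1", home + away))
        assert "m1" in members_on_date(iv, "A", day(-1))
        assert "m1" not in members_on_date(iv, "A", day(0))
        assert "m1" in members_on_date(iv, "B", day(0))

    @pytest.mark.parametrize("query, expected", [(0, 1), (99, 100)])
    def test_tenure_is_inclusive_day_count(self, query, expected):
        assert tenure_on_date(self._intervals(), "m1", day(query)) == expected

    def test_tenure_zero_for_nonmember(self):
        assert tenure_on_date(self._intervals(), "m1", day(-1)) == 0

    def test_female_philopatry(self):
        f = Individual("f1", "female", day(-3000), None, "G")
        idx = MembershipIndex([f], [])
        assert "f1" in idx.members_on_date("G", day(0))
        assert idx.members_on_date("H", day(0)) == set()


class TestGroupComposition:
    def _world(self, n_f=20, n_m=10, male_age=2000):
        onset = day(0)
        inds = [Individual(f"f{i}", "female", day(-2000), None, "G")
                for i in range(n_f)]
        males = [Individual(f"m{i}", "male", day(-male_age), None, "X")
                 for i in range(n_m)]
        iv = [build_membership_intervals(
            sightings(m.id, [(k, "G") for k in range(-400, 300, 3)]))[0]
            for m in males]
        season = SeasonCalendar("G", 2005, onset, day(99))
        return inds + males, iv, season

    def test_age_threshold_is_strict(self):
        """A male aged exactly 1250 days at onset is not yet a breeder."""
        inds, iv, season = self._world(n_f=0, n_m=1, male_age=1250)
        assert breeding_group_composition("G", season, inds, iv) == (0, 0)
        inds, iv, season = self._world(n_f=0, n_m=1, male_age=1251)
        assert breeding_group_composition("G", season, inds, iv) == (0, 1)

    def test_counts_and_size(self):
        inds, iv, season = self._world(n_f=20, n_m=10)
        n_f, n_m = breeding_group_composition("G", season, inds, iv)
        assert (n_f, n_m) == (20, 10)

    def test_sex_ratio_constant_counts(self):
        inds, iv, season = self._world(n_f=20, n_m=10)
        assert sex_ratio("G", season, inds, iv) == pytest.approx(2.0)

    def test_sex_ratio_daily_average_with_mid_season_departures(self):
        """10 females all season; 10 males for the first half and 5 for the
        second -> 10 / 7.5."""
        inds = [Individual(f"f{i}", "female", day(-2000), None, "G")
                for i in range(10)]
        males = [Individual(f"m{i}", "male", day(-2000), None, "X")
                 for i in range(10)]
        iv = []
        for i, m in enumerate(males):
            if i >= 5:  # five males transfer away at exact mid-season
                spec = ([(k, "G") for k in range(-400, 50)]
                        + [(k, "H") for k in range(50, 300)])
            else:
                spec = [(k, "G") for k in range(-400, 300)]
            iv.extend(build_membership_intervals(sightings(m.id, spec)))
        season = SeasonCalendar("G", 2005, day(0), day(99))
        r = sex_ratio("G", season, inds + males, iv)
        assert r == pytest.approx(10.0 / 7.5, rel=1e-12)

    def test_sex_ratio_undefined_without_males(self):
        inds, iv, season = self._world(n_f=5, n_m=0)
        with pytest.raises(ValueError, match="sex ratio undefined"):
            sex_ratio("G", season, inds, iv)

    def test_daily_counts_match_bruteforce(self):
        """Vectorized daily tabulation equals a per-day, per-individual scan
        on a randomized 3-group history."""
        rng = np.random.default_rng(11)
        inds, intervals = [], []
        for i in range(40):
            g = f"G{rng.integers(3)}"
            if rng.random() < 0.5:
                inds.append(Individual(f"f{i}", "female",
                                       day(-int(rng.integers(300, 6000))),
                                       None, g))
            else:
                birth = day(-int(rng.integers(1300, 6000)))
                inds.append(Individual(f"m{i}", "male", birth, None, "X"))
                s = int(rng.integers(-300, 50))
                sl = sightings(f"m{i}", [(k, g) for k in range(s, s + 200, 2)])
                intervals.extend(build_membership_intervals(sl))
        idx = MembershipIndex(inds, intervals)
        days = np.arange(day(0).toordinal(), day(60).toordinal())
        for g in ("G0", "G1", "G2"):
            n_f, n_m = idx.daily_mature_counts(g, days)
            for j, o in enumerate(days):
                bf, bm = _oracles.brute_mature_counts(inds, intervals, g,
                                                      int(o))
                assert (n_f[j], n_m[j]) == (bf, bm)


class TestOffspringFilter:
    def _births(self):
        rows = [
            ("i1", "mom1", day(0), "G"),    # died at 100 days
            ("i2", "mom2", day(0), "G"),    # healthy, genotyped
            ("i3", "mom3", day(0), "G"),    # not genotyped
            ("i4", "mom4", day(0), "G"),    # removed with mother, day 200
            ("i5", "mom5", day(0), "F"),    # group fissioned mid-study
        ]
        births = pd.DataFrame(rows, columns=["offspring", "mother",
                                             "birth_date", "natal_group"])
        inds = [
            Individual("i1", "male", day(0), day(100), "G"),
            Individual("i2", "female", day(0), None, "G"),
            Individual("i3", "male", day(0), None, "G"),
            Individual("i4", "female", day(0), day(200), "G"),
            Individual("i5", "male", day(0), None, "F"),
            Individual("mom1", "female", day(-3000), None, "G"),
            Individual("mom2", "female", day(-3000), None, "G"),
            Individual("mom3", "female", day(-3000), None, "G"),
            Individual("mom4", "female", day(-3000), day(200), "G"),
            Individual("mom5", "female", day(-3000), None, "F"),
        ]
        return births, inds

    def test_each_exclusion_reason(self):
        births, inds = self._births()
        retained, excluded = filter_offspring_cohort(
            births, inds, genotyped={"i1", "i2", "i4", "i5"},
            persistent_groups={"G"})
        assert list(retained["offspring"]) == ["i2"]
        reasons = dict(zip(excluded["offspring"], excluded["reason"]))
        assert reasons == {"i1": "died<1y", "i3": "ungenotyped",
                           "i4": "removed_with_mother<1y",
                           "i5": "group_not_persistent"}

    def test_row_conservation(self):
        births, inds = self._births()
        retained, excluded = filter_offspring_cohort(
            births, inds, genotyped=set(), persistent_groups={"G", "F"})
        assert len(retained) + len(excluded) == len(births)
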