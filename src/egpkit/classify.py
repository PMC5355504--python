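"""Conception windows and within-group / extra-group offspring classification.

The conception window is obtained by subtracting the gestation length
(mean +- SD) from the birth date and discretizing to whole days: with the
default gestation of 166.5 +- 7.4 days the window spans birth - 174 to
birth - 160 days, i.e. 15 consecutive dates.  The evaluation window for
extra-group paternity extends the conception window by 30 days on each side
(75 days in total) so that an ordinary migration around conception is not
mistaken for an extra-group fertilization: an offspring is within-group if
its sire was a member of the offspring's group on at least one of those 75
days, extra-group otherwise.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._dates import as_date, from_ordinal, ordinal
from .demography import MembershipIndex, SeasonCalendar

WITHIN_GROUP = "within_group"
EXTRA_GROUP = "extra_group"


@dataclass(frozen=True)
class ConceptionParams:
    """Gestation-length distribution and the migration buffer."""

    gestation_mean_days: float = 166.5
    gestation_sd_days: float = 7.4
    egp_buffer_days: int = 30

    def __post_init__(self):
        if self.gestation_mean_days <= 0 or self.gestation_sd_days <= 0:
            raise ValueError("gestation parameters must be positive")
        if self.egp_buffer_days < 0:
            raise ValueError("egp_buffer_days must be non-negative")

    @property
    def min_offset_days(self) -> int:
        """Smallest birth-minus-conception offset retained in the window."""
        return math.ceil(self.gestation_mean_days - self.gestation_sd_days)

    @property
    def window_days(self) -> int:
        """Number of integer day offsets in a span of 2*SD (14.8 -> 15)."""
        return math.floor(2.0 * self.gestation_sd_days) + 1


@dataclass(frozen=True)
class ConceptionWindow:
    """Plausible conception dates for one offspring (closed interval)."""

    offspring_id: Optional[str]
    start_date: datetime.date
    end_date: datetime.date

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def midpoint_ordinal(self) -> float:
        return 0.5 * (self.start_date.toordinal() + self.end_date.toordinal())

    def dates(self) -> set:
        o0, o1 = self.start_date.toordinal(), self.end_date.toordinal()
        return {from_ordinal(o) for o in range(o0, o1 + 1)}


@dataclass(frozen=True)
class EGPClassification:
    offspring_id: str
    sire_id: str
    status: str
    window_start: datetime.date
    window_end: datetime.date
    overlap_days: int


def conception_window(birth_date, params: ConceptionParams = ConceptionParams(),
                      offspring_id: Optional[str] = None) -> ConceptionWindow:
    """15-day conception window: birth minus gestation mean +- SD, whole days.

    The window covers offsets ``ceil(mean - sd)`` through
    ``ceil(mean - sd) + floor(2 sd)`` days before birth ([160, 174] under the
    defaults), the unique whole-day discretization with the correct span.
    """
    b = ordinal(birth_date)
    lo_off = params.min_offset_days
    hi_off = lo_off + params.window_days - 1
    return ConceptionWindow(offspring_id, from_ordinal(b - hi_off),
                            from_ordinal(b - lo_off))


def egp_window(cw: ConceptionWindow,
               params: ConceptionParams = ConceptionParams()):
    """Evaluation window for extra-group paternity: the conception window
    padded by ``egp_buffer_days`` on each side (75 days under defaults)."""
    b = params.egp_buffer_days
    return (from_ordinal(cw.start_date.toordinal() - b),
            from_ordinal(cw.end_date.toordinal() + b))


def classify_offspring(offspring_id: str, sire_id: Optional[str],
                       natal_group: str, birth_date,
                       index: MembershipIndex,
                       params: ConceptionParams = ConceptionParams()
                       ) -> Optional[EGPClassification]:
    """Classify one offspring as within-group or extra-group.

    Within-group iff the sire was a member of the offspring's natal group on
    at least one day of the padded conception window (which deliberately
    includes sires that immigrated or emigrated during the window).  Returns
    ``None`` when no sire is assigned (unclassifiable; callers must log it).
    """
    if sire_id is None:
        return None
    cw = conception_window(birth_date, params, offspring_id)
    w0, w1 = egp_window(cw, params)
    overlap = index.membership_overlap_days(sire_id, natal_group, w0, w1)
    status = WITHIN_GROUP if overlap >= 1 else EXTRA_GROUP
    return EGPClassification(offspring_id, sire_id, status, w0, w1, overlap)


def classify_all(births: pd.DataFrame, assignments: pd.DataFrame,
                 index: MembershipIndex,
                 params: ConceptionParams = ConceptionParams()):
    """Classify every offspring with an assigned sire.

    ``births`` must hold ``offspring, mother, birth_date, natal_group``;
    ``assignments`` holds ``offspring, sire`` (from
    :func:`egpkit.paternity.assign_all`).  Returns ``(classifications,
    dropped)`` DataFrames; dropped rows (no sire) carry a reason.
    """
    merged = births.merge(assignments[["offspring", "sire"]], on="offspring",
                          how="left")
    rows, dropped = [], []
    for rec in merged.itertuples(index=False):
        sire = rec.sire if isinstance(rec.sire, str) else None
        c = classify_offspring(rec.offspring, sire, rec.natal_group,
                               rec.birth_date, index, params)
        if c is None:
            dropped.append((rec.offspring, "no_assigned_sire"))
            continue
        rows.append((c.offspring_id, c.sire_id, c.status,
                     c.window_start.isoformat(), c.window_end.isoformat(),
                     c.overlap_days))
    out = pd.DataFrame(rows, columns=["offspring", "sire", "status",
                                      "window_start", "window_end",
                                      "overlap_days"])
    drop = pd.DataFrame(dropped, columns=["offspring", "reason"])
    return out, drop


def assign_cohort(birth_date, group: str,
                  seasons: Sequence[SeasonCalendar],
                  params: ConceptionParams = ConceptionParams()) -> int:
    """Birth cohort of an offspring: the group's season whose mating window
    is closest to (normally containing) the conception-window midpoint."""
    cw = conception_window(birth_date, params)
    mid = cw.midpoint_ordinal
    best, best_dist = None, None
    for s in seasons:
        if s.group != group:
            continue
        o0 = s.mating_season_onset.toordinal()
        o1 = s.mating_season_end.toordinal()
        dist = max(o0 - mid, mid - o1, 0.0)
        if best_dist is None or dist < best_dist:
            best, best_dist = s.cohort_year, dist
    if best is None:
        raise ValueError(f"no season calendar entries for group {group!r}")
    return best


def tabulate_egp(classifications: pd.DataFrame) -> pd.DataFrame:
    """Per group-cohort EGP counts and percentages with marginal totals.

    ``classifications`` must carry ``group, cohort, status`` columns.  The
    percentage is ``n_egp / (n_egp + n_within) * 100``.  Rows are
    (cohort x group) cells plus ``Total`` rows/columns.
    """
    df = classifications.copy()
    df["is_egp"] = (df["status"] == EXTRA_GROUP).astype(int)
    cells = (df.groupby(["group", "cohort"], as_index=False)
               .agg(n_egp=("is_egp", "sum"), n_total=("is_egp", "size")))
    cells["n_within"] = cells["n_total"] - cells["n_egp"]
    totals_g = (cells.groupby("group", as_index=False)
                [["n_egp", "n_within", "n_total"]].sum())
    totals_g["cohort"] = "Total"
    totals_c = (cells.groupby("cohort", as_index=False)
                [["n_egp", "n_within", "n_total"]].sum())
    totals_c["group"] = "Total"
    grand = pd.DataFrame([{
        "group": "Total", "cohort": "Total",
        "n_egp": cells["n_egp"].sum(), "n_within": cells["n_within"].sum(),
        "n_total": cells["n_total"].sum(),
    }])
    out = pd.concat([cells, totals_g, totals_c, grand], ignore_index=True)
    out["pct_egp"] = 100.0 * out["n_egp"] / out["n_total"]
    return out[["group", "cohort", "n_egp", "n_within", "n_total", "pct_egp"]]
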