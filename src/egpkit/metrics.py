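"""Group-season covariates: female reproductive synchrony and group instability.

Synchrony
    For one group and season, pool the 15-day conception windows of every
    female observed with a live birth and count the unique dates U on which
    at least one female was estimated to be in estrus.  The synchrony index
    is 15 / U: it equals 1 when all windows coincide and decreases toward
    15 / (15 n) as the n windows separate.

Instability
    Membership loss on day d is the tenure-weighted proportion of males that
    disappeared since the previous day (sum of the leavers' previous-day
    residence durations over the sum of all males' previous-day durations);
    membership gain is the number of newly appeared males over the current
    day's mature group size.  Both daily series are averaged over the mating
    season with weights 1 / (t + 1), t days after onset, so disturbances
    near the onset weigh most; the instability index is the sum of the two
    weighted averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from ._dates import ordinal
from .classify import ConceptionWindow
from .demography import MembershipIndex, SeasonCalendar


@dataclass(frozen=True)
class SynchronyResult:
    group: Optional[str]
    cohort: Optional[int]
    n_breeding_females: int
    unique_estrous_days: int
    synchrony: float


@dataclass(frozen=True)
class InstabilityResult:
    group: Optional[str]
    cohort: Optional[int]
    daily_loss: np.ndarray
    daily_gain: np.ndarray
    weighted_loss: float
    weighted_gain: float
    instability: float


def female_synchrony(windows: Sequence[ConceptionWindow],
                     group: Optional[str] = None,
                     cohort: Optional[int] = None) -> SynchronyResult:
    """Synchrony index 15 / U from live-birth conception windows.

    ``U`` is the cardinality of the union of the windows' dates.  Raises on
    an empty window set (a group-season without live births is dropped).
    """
    if len(windows) == 0:
        raise ValueError("synchrony undefined without live births")
    lengths = {w.n_days for w in windows}
    if len(lengths) != 1:
        raise ValueError("conception windows must share one length")
    n_days = lengths.pop()
    dates: set[int] = set()
    for w in windows:
        dates.update(range(w.start_date.toordinal(),
                           w.end_date.toordinal() + 1))
    u = len(dates)
    return SynchronyResult(group, cohort, len(windows), u, n_days / u)


def membership_loss_daily(group: str, date, index: MembershipIndex) -> float:
    """Tenure-weighted proportion of male membership lost since yesterday.

    0 by convention when the group held no males yesterday.
    """
    o = ordinal(date)
    ids, present, tenure = index.male_presence_matrix(group, np.array([o - 1, o]))
    denom = tenure[present[:, 0], 0].sum()
    if denom == 0:
        return 0.0
    lost = present[:, 0] & ~present[:, 1]
    return float(tenure[lost, 0].sum() / denom)


def membership_gain_daily(group: str, date, index: MembershipIndex,
                          maturity_age_days: int = 1250) -> float:
    """Newly appeared males today over today's mature group size."""
    o = ordinal(date)
    ids, present, _ = index.male_presence_matrix(group, np.array([o - 1, o]))
    gained = int((present[:, 1] & ~present[:, 0]).sum())
    if gained == 0:
        return 0.0
    n_f, n_m = index.daily_mature_counts(group, np.array([o]), maturity_age_days)
    size = int(n_f[0] + n_m[0])
    if size == 0:
        return 0.0
    return gained / size


def weighted_instability(daily_losses, daily_gains,
                         season: Optional[SeasonCalendar] = None,
                         group: Optional[str] = None,
                         cohort: Optional[int] = None) -> InstabilityResult:
    """Combine daily loss/gain series into the season instability index.

    Day t (0 at mating-season onset) receives weight 1 / (t + 1); each
    series is averaged with normalized weights and the two averages summed.
    """
    loss = np.asarray(daily_losses, dtype=float)
    gain = np.asarray(daily_gains, dtype=float)
    if loss.shape != gain.shape:
        raise ValueError("loss and gain series must have equal length")
    t = np.arange(len(loss))
    w = 1.0 / (t + 1.0)
    wsum = w.sum()
    wl = float((w * loss).sum() / wsum)
    wg = float((w * gain).sum() / wsum)
    if cohort is None and season is not None:
        cohort = season.cohort_year
    return InstabilityResult(group, cohort, loss, gain, wl, wg, wl + wg)


def group_instability(group: str, season: SeasonCalendar,
                      index: MembershipIndex,
                      maturity_age_days: int = 1250) -> InstabilityResult:
    """Season instability for one group, computed from membership intervals."""
    o0 = season.mating_season_onset.toordinal()
    o1 = season.mating_season_end.toordinal()
    days = np.arange(o0 - 1, o1 + 1)  # previous day needed for the onset day
    ids, present, tenure = index.male_presence_matrix(group, days)
    prev, cur = present[:, :-1], present[:, 1:]
    tprev = tenure[:, :-1]
    denom_loss = (tprev * prev).sum(axis=0)
    lost = ((prev & ~cur) * tprev).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        daily_loss = np.where(denom_loss > 0, lost / denom_loss, 0.0)
    gained = (cur & ~prev).sum(axis=0).astype(float)
    n_f, n_m = index.daily_mature_counts(group, days[1:], maturity_age_days)
    size = (n_f + n_m).astype(float)
    daily_gain = np.where(size > 0, gained / np.where(size > 0, size, 1.0), 0.0)
    return weighted_instability(daily_loss, daily_gain, season, group=group)
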