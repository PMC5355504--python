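"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(n^3) hull construction, per-day
per-individual membership scans, per-locus enumeration — and shares no code
with the package internals beyond the public dataclasses.
"""

from __future__ import annotations

import numpy as np


# -- convex hull --------------------------------------------------------

def brute_force_hull_area(points) -> float:
    """Hull area via O(n^3) edge testing + shoelace on the ordered boundary."""
    pts = [tuple(p) for p in np.asarray(points, dtype=float)]
    uniq = sorted(set(pts))
    n = len(uniq)
    hull_edges = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a, b = uniq[i], uniq[j]
            left = right = 0
            ok = True
            for k in range(n):
                if k in (i, j):
                    continue
                c = uniq[k]
                cross = ((b[0] - a[0]) * (c[1] - a[1])
                         - (b[1] - a[1]) * (c[0] - a[0]))
                if cross > 1e-12:
                    left += 1
                elif cross < -1e-12:
                    right += 1
                if left and right:
                    ok = False
                    break
            if ok and left >= 0 and right == 0:
                hull_edges.append((a, b))
    nxt = dict(hull_edges)
    if not nxt:
        return 0.0
    start = hull_edges[0][0]
    ordered = [start]
    cur = nxt[start]
    while cur != start and len(ordered) <= len(nxt) + 1:
        ordered.append(cur)
        cur = nxt[cur]
    area = 0.0
    for (x1, y1), (x2, y2) in zip(ordered, ordered[1:] + ordered[:1]):
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


# -- membership tabulations --------------------------------------------

def _covers(iv, o: int) -> bool:
    s = iv.start_date.toordinal()
    e = iv.end_date.toordinal() if iv.end_date is not None else None
    return s <= o and (e is None or o <= e)


def brute_members(intervals, group: str, o: int) -> set:
    """Males whose interval covers ordinal day o in the group."""
    return {iv.individual_id for iv in intervals
            if iv.group == group and _covers(iv, o)}


def brute_tenure(intervals, individual_id: str, o: int) -> int:
    for iv in intervals:
        if iv.individual_id == individual_id and _covers(iv, o):
            return o - iv.start_date.toordinal() + 1
    return 0


def brute_mature_counts(individuals, intervals, group: str, o: int,
                        maturity: int = 1250):
    n_f = sum(1 for i in individuals
              if i.sex == "female" and i.natal_group == group
              and i.birth_date.toordinal() <= o
              and (i.death_date is None or o <= i.death_date.toordinal())
              and o - i.birth_date.toordinal() > maturity)
    n_m = 0
    for mid in brute_members(intervals, group, o):
        ind = next(i for i in individuals if i.id == mid)
        if o - ind.birth_date.toordinal() > maturity:
            n_m += 1
    return n_f, n_m


def brute_instability(individuals, intervals, group: str, onset: int,
                      end: int, maturity: int = 1250):
    """Daily loss/gain series and the weighted instability index."""
    losses, gains = [], []
    for o in range(onset, end + 1):
        yesterday = brute_members(intervals, group, o - 1)
        today = brute_members(intervals, group, o)
        denom = sum(brute_tenure(intervals, m, o - 1) for m in yesterday)
        lost = sum(brute_tenure(intervals, m, o - 1)
                   for m in yesterday - today)
        losses.append(lost / denom if denom else 0.0)
        new = len(today - yesterday)
        n_f, n_m = brute_mature_counts(individuals, intervals, group, o,
                                       maturity)
        size = n_f + n_m
        gains.append(new / size if (new and size) else 0.0)
    w = [1.0 / (t + 1.0) for t in range(len(losses))]
    wsum = sum(w)
    wl = sum(wi * li for wi, li in zip(w, losses)) / wsum
    wg = sum(wi * gi for wi, gi in zip(w, gains)) / wsum
    return losses, gains, wl, wg, wl + wg


# -- Mendelian trio check ----------------------------------------------

def brute_trio_mismatches(off, mom, dad) -> int:
    """Per-locus enumeration of Mendelian-consistent allele assignments.

    ``off``, ``mom``, ``dad`` are (L, 2) arrays with -1 for untyped loci.
    Loci where the offspring shares no allele with the mother are maternal
    conflicts and are skipped.
    """
    n = 0
    for loc in range(off.shape[0]):
        o, m, d = off[loc], mom[loc], dad[loc]
        if -1 in o or -1 in m or -1 in d:
            continue
        if not (o[0] in m or o[1] in m):
            continue  # maternal conflict, not attributed to the candidate
        consistent = False
        for maternal, paternal in ((o[0], o[1]), (o[1], o[0])):
            if maternal in m and paternal in d:
                consistent = True
        if not consistent:
            n += 1
    return n
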