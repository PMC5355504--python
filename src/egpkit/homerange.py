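"""Minimum-convex-polygon home ranges and between-group male-density overlap.

Each group-season home range is the convex hull of the group's daily
location records (planar coordinates; the study area is small enough that
no projection handling is needed).  A fixed grid (default 25 m cells,
anchored at the origin) is laid over each range; a cell belongs to a range
when its center lies inside or on the hull.  The group's male density is
males per occupied cell, and the overlap index of a focal group is the sum,
over its cells, of the densities of every other group occupying that cell.
The overlap index feeds the model as a log offset, so a zero value is an
error unless an explicit floor is opted into.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon


@dataclass(frozen=True)
class HomeRange:
    group: str
    season: Optional[int]
    polygon: Polygon
    cell_size: float
    cells: frozenset

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass(frozen=True)
class OverlapResult:
    group: str
    season: Optional[int]
    cell_density: Dict[Tuple[int, int], float]
    overlap_index: float


def minimum_convex_polygon(points) -> Polygon:
    """Convex hull of location points; errors on < 3 non-collinear points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        raise ValueError("home range needs at least 3 location points")
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("all location points are collinear")
    return hull


def rasterize(polygon: Polygon, cell_size: float = 25.0,
              origin: Tuple[float, float] = (0.0, 0.0)) -> frozenset:
    """Grid cells whose center lies inside or on the polygon.

    Cells are indexed by integer (i, j): cell (i, j) spans
    ``[origin + i*s, origin + (i+1)*s)`` in x and likewise in y, with center
    at ``origin + (i + 1/2) * s``.  Boundary centers count as inside.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    ox, oy = origin
    minx, miny, maxx, maxy = polygon.bounds
    i0 = int(np.floor((minx - ox) / cell_size)) - 1
    i1 = int(np.ceil((maxx - ox) / cell_size)) + 1
    j0 = int(np.floor((miny - oy) / cell_size)) - 1
    j1 = int(np.ceil((maxy - oy) / cell_size)) + 1
    ii, jj = np.meshgrid(np.arange(i0, i1 + 1), np.arange(j0, j1 + 1),
                         indexing="ij")
    cx = ox + (ii + 0.5) * cell_size
    cy = oy + (jj + 0.5) * cell_size
    centers = shapely.points(cx.ravel(), cy.ravel())
    inside = shapely.covers(polygon, centers)  # covers: boundary included
    return frozenset(zip(ii.ravel()[inside].tolist(),
                         jj.ravel()[inside].tolist()))


def home_range(group: str, points, cell_size: float = 25.0,
               season: Optional[int] = None,
               origin: Tuple[float, float] = (0.0, 0.0)) -> HomeRange:
    poly = minimum_convex_polygon(points)
    return HomeRange(group, season, poly, cell_size,
                     rasterize(poly, cell_size, origin))


def male_density(hr: HomeRange, n_males: int) -> float:
    """Males per grid cell of the home range."""
    if hr.n_cells == 0:
        raise ValueError(f"{hr.group}: home range rasterized to zero cells")
    return n_males / hr.n_cells


def overlap_index(focal: HomeRange,
                  others: Mapping[str, Tuple[HomeRange, float]]
                  ) -> OverlapResult:
    """Summed other-group male density over the focal home range.

    ``others`` maps group id -> (home range, male density); the focal group
    is skipped if present.  The index is additive over groups and over
    cells, and zero iff no other range touches the focal one (the pipeline
    refuses a zero when building the log offset unless a floor is opted in).
    """
    cell_density: Dict[Tuple[int, int], float] = {}
    for g, (hr, dens) in others.items():
        if g == focal.group:
            continue
        for cell in hr.cells & focal.cells:
            cell_density[cell] = cell_density.get(cell, 0.0) + dens
    return OverlapResult(focal.group, focal.season, cell_density,
                         float(sum(cell_density.values())))


def seasonal_overlap_table(locations, seasons, male_counts,
                           cell_size: float = 25.0,
                           origin: Tuple[float, float] = (0.0, 0.0),
                           zero_floor: Optional[float] = None):
    """Overlap index for every (group, cohort) cell.

    Parameters
    ----------
    locations
        DataFrame ``group, date, x, y`` of daily location records.
    seasons
        Sequence of :class:`egpkit.demography.SeasonCalendar`.
    male_counts
        Mapping ``(group, cohort_year) -> n_males`` (breeding males at
        season onset).

    Returns a DataFrame ``group, cohort, n_cells, male_density, overlap``.
    """
    import pandas as pd

    from ._dates import to_ordinals

    loc = locations.copy()
    loc["_ord"] = to_ordinals(loc["date"].to_numpy())
    out = []
    cohorts = sorted({s.cohort_year for s in seasons})
    by_cohort: Dict[int, Dict[str, Tuple[HomeRange, float]]] = {}
    for year in cohorts:
        ranges: Dict[str, Tuple[HomeRange, float]] = {}
        for s in seasons:
            if s.cohort_year != year:
                continue
            o0 = s.mating_season_onset.toordinal()
            o1 = s.mating_season_end.toordinal()
            sel = loc[(loc["group"] == s.group) & (loc["_ord"] >= o0)
                      & (loc["_ord"] <= o1)]
            if len(sel) < 3:
                raise ValueError(
                    f"{s.group}/{year}: fewer than 3 location records")
            hr = home_range(s.group, sel[["x", "y"]].to_numpy(), cell_size,
                            season=year, origin=origin)
            dens = male_density(hr, male_counts[(s.group, year)])
            ranges[s.group] = (hr, dens)
        by_cohort[year] = ranges
    for year, ranges in by_cohort.items():
        for g, (hr, dens) in ranges.items():
            ov = overlap_index(hr, ranges)
            total = ov.overlap_index
            if total == 0.0:
                if zero_floor is None:
                    raise ValueError(
                        f"{g}/{year}: zero home-range overlap breaks the log "
                        "offset; pass zero_floor to opt into a floor")
                total = zero_floor
            out.append((g, year, hr.n_cells, dens, total))
    return pd.DataFrame(out, columns=["group", "cohort", "n_cells",
                                      "male_density", "overlap"])
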