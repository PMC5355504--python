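"""Synthetic island population with a recorded truth log.

Generates every input table the pipeline consumes — census, male sightings,
season calendar, genotypes, births and daily group locations — for a closed
island population of six social groups followed over nine annual birth
cohorts, with the statistical structure the analysis assumes:

* group sizes ~ Normal(82.2, 43.7) and breeding sex ratios ~ Normal(1.615,
  0.318) at founding; philopatric females; males dispersing from the natal
  group at ~4 years and migrating between neighboring groups thereafter;
* ~86% of mature females conceiving per season, gestation Normal(166.5,
  7.4) days;
* ~28 microsatellite loci with Dirichlet allele frequencies, Mendelian
  inheritance, optional per-allele genotyping error and a 27.6 +- 1.6
  typed-loci panel distribution;
* each conception is an extra-group fertilization with probability
  expit(g0 + g' z), a log-linear function of the group-season covariates
  (sex ratio, size, synchrony, instability and the sex-ratio x size
  interaction) computed on the generator's own truth, so the downstream
  model has a known signal to recover.

Everything is seeded from a single root seed fanned out per sub-generator;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._dates import from_ordinal, ordinal
from .demography import (FEMALE, MALE, Individual, MembershipIndex,
                         MembershipInterval, SeasonCalendar)
from .metrics import group_instability

_D = datetime.date


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass
class SimConfig:
    """Generator configuration; defaults state the emulated population."""

    n_groups: int = 6
    n_cohorts: int = 9
    first_cohort_year: int = 2004
    seed: int = 0

    # demography
    group_size_mean: float = 82.2
    group_size_sd: float = 43.7
    min_group_size: int = 25
    sex_ratio_mean: float = 1.615
    sex_ratio_sd: float = 0.318
    female_birth_prob: float = 0.86
    gestation_mean_days: float = 166.5
    gestation_sd_days: float = 7.4
    season_length_days: int = 100
    immature_male_frac: float = 0.35
    natal_dispersal_age_days: int = 1460
    male_annual_death_prob: float = 0.02
    migration_prob: float = 0.04
    excursion_prob: float = 0.10
    prospecting_arrival_prob: float = 0.25
    min_residence_days: int = 90
    sighting_interval_days: int = 3
    observation_lead_years: int = 3
    infant_death_prob: float = 0.14
    removed_with_mother_prob: float = 0.02
    ungenotyped_prob: float = 0.005
    # the island's removal program culls surviving study-born juveniles
    # before maturity, keeping the breeding pool stationary
    juvenile_cull_age_range: Tuple[int, int] = (400, 1000)

    # genetics
    n_loci: int = 28
    n_alleles: int = 8
    dirichlet_alpha: float = 1.0
    genotyping_error_rate: float = 0.0
    panel_mean: float = 27.6
    panel_sd: float = 1.6
    panel_min: int = 13

    # extra-group paternity model: intercept, z(sex_ratio), z(size),
    # z(synchrony), z(instability), z(sex_ratio)*z(size)
    egp_gamma: Tuple[float, float, float, float, float, float] = (
        _logit(0.16), 0.0, 0.0, 0.0, 0.0, 0.0)
    egp_min_sire_age_days: int = 1310  # 1250 + safety margin at conception

    # geography (planar meters; the island is ~15.2 ha)
    range_ring_radius: float = 130.0
    range_center_xy: Tuple[float, float] = (400.0, 400.0)
    range_scatter_sd: float = 60.0

    def __post_init__(self):
        for name in ("female_birth_prob", "migration_prob", "excursion_prob",
                     "prospecting_arrival_prob", "infant_death_prob",
                     "removed_with_mother_prob", "ungenotyped_prob",
                     "genotyping_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.group_size_mean <= 0 or self.min_group_size <= 0:
            raise ValueError("group sizes must be positive")

    # -- timeline ------------------------------------------------------
    def season_onset(self, cohort_year: int) -> _D:
        return _D(cohort_year - 1, 7, 1)

    def season_end(self, cohort_year: int) -> _D:
        return from_ordinal(self.season_onset(cohort_year).toordinal()
                            + self.season_length_days - 1)

    @property
    def cohort_years(self) -> List[int]:
        return list(range(self.first_cohort_year,
                          self.first_cohort_year + self.n_cohorts))

    @property
    def observation_start(self) -> _D:
        y = self.first_cohort_year - 1 - self.observation_lead_years
        return _D(y, 7, 1)

    @property
    def observation_end(self) -> _D:
        return _D(self.first_cohort_year + self.n_cohorts - 1, 7, 1)

    def groups(self) -> List[str]:
        return [f"G{i + 1}" for i in range(self.n_groups)]

    def neighbors(self, group: str) -> List[str]:
        """Ring adjacency by default (the real geometry is unavailable)."""
        gs = self.groups()
        i = gs.index(group)
        if len(gs) == 1:
            return [group]
        if len(gs) == 2:
            return [gs[1 - i]]
        return [gs[(i - 1) % len(gs)], gs[(i + 1) % len(gs)]]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "egp_gamma" in raw:
            raw["egp_gamma"] = tuple(float(v) for v in raw["egp_gamma"])
        if "range_center_xy" in raw:
            raw["range_center_xy"] = tuple(raw["range_center_xy"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml
        d = dataclasses.asdict(self)
        d["egp_gamma"] = list(self.egp_gamma)
        d["range_center_xy"] = list(self.range_center_xy)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class TruthLog:
    """Ground truth: per-offspring parentage and per-male residence."""

    parentage: pd.DataFrame     # offspring, mother, sire, conception_date,
                                # egp, group, cohort
    intervals: List[MembershipInterval]
    covariates: pd.DataFrame    # group, cohort, size, sex_ratio, synchrony,
                                # instability, p_egp


@dataclass
class SimData:
    """All emitted input tables plus the truth log."""

    config: SimConfig
    census: pd.DataFrame
    sightings: pd.DataFrame
    seasons: pd.DataFrame
    births: pd.DataFrame
    genotypes: pd.DataFrame
    locations: pd.DataFrame
    truth: TruthLog

    def individuals(self) -> List[Individual]:
        out = []
        for r in self.census.itertuples(index=False):
            death = None if r.death_date in ("", None) else r.death_date
            out.append(Individual(r.id, r.sex, r.birth_date, death,
                                  r.natal_group))
        return out

    def season_calendar(self) -> List[SeasonCalendar]:
        return [SeasonCalendar(r.group, int(r.cohort_year), r.mating_onset,
                               r.mating_end)
                for r in self.seasons.itertuples(index=False)]


@dataclass
class _Male:
    id: str
    birth: int                      # ordinals throughout
    natal_group: str
    death: Optional[int]
    segments: List[Tuple[str, int, Optional[int]]]  # (group, start, end)
    prospecting_arrivals: set = field(default_factory=set)  # segment starts
    excursions: List[Tuple[int, str]] = field(default_factory=list)


def simulate_population(config: SimConfig, rng: np.random.Generator):
    """Build founder adults, male life histories and the census sightings.

    Returns ``(individuals, males, sightings_df, seasons_df)`` where
    ``males`` carries the truth residence segments.
    """
    obs0 = config.observation_start.toordinal()
    obs1 = config.observation_end.toordinal()
    onset1 = config.season_onset(config.first_cohort_year).toordinal()
    groups = config.groups()

    individuals: List[Individual] = []
    males: List[_Male] = []
    for gi, g in enumerate(groups):
        size = max(config.min_group_size,
                   rng.normal(config.group_size_mean, config.group_size_sd))
        ratio = float(np.clip(rng.normal(config.sex_ratio_mean,
                                         config.sex_ratio_sd), 0.9, 2.8))
        n_f = int(round(size * ratio / (1.0 + ratio)))
        n_m = max(3, int(round(size)) - n_f)
        # part of the male quota enters as immature natal males that mature
        # (and disperse) during the observation lead, so the mature pool
        # stays near the drawn target once they have grown in
        n_imm = int(round(config.immature_male_frac * n_m))
        n_m_founder = max(3, n_m - n_imm)
        for k in range(n_f):
            birth = onset1 - int(rng.integers(1460, 6570))
            individuals.append(Individual(f"F-{g}-{k:03d}", FEMALE,
                                          from_ordinal(birth), None, g))
        for k in range(n_m_founder):
            birth = onset1 - int(rng.integers(1825, 5500))
            natal = groups[(gi + int(rng.integers(1, len(groups)))) %
                           len(groups)] if len(groups) > 1 else g
            males.append(_Male(f"M-{g}-{k:03d}", birth, natal, None,
                               [(g, obs0, None)]))
        for k in range(n_imm):
            birth = obs0 - int(rng.integers(200, 1200))
            males.append(_Male(f"J-{g}-{k:03d}", birth, g, None,
                               [(g, obs0, None)]))

    season_years = range(config.observation_start.year + 1,
                         config.first_cohort_year + config.n_cohorts)
    for m in males:
        # mortality: one uniform death date per hazard year
        for year in range(config.observation_start.year,
                          config.observation_end.year + 1):
            if rng.random() < config.male_annual_death_prob:
                d = _D(year, 1, 1).toordinal() + int(rng.integers(0, 365))
                if obs0 < d < obs1:
                    m.death = d
                    break
        # planned moves: natal dispersal then seasonal migrations
        moves: List[int] = []
        if m.id.startswith("J-"):
            moves.append(m.birth + config.natal_dispersal_age_days)
        for year in season_years:
            if rng.random() < config.migration_prob:
                onset = _D(year, 7, 1).toordinal()
                moves.append(onset - 45
                             + int(rng.integers(0,
                                                config.season_length_days + 45)))
        last = obs0
        for mv in sorted(moves):
            if mv - last < config.min_residence_days:
                continue
            if mv > obs1 - 75 or (m.death is not None and mv >= m.death):
                continue
            cur = m.segments[-1][0]
            target = config.neighbors(cur)[
                int(rng.integers(0, len(config.neighbors(cur))))]
            if target == cur:
                continue
            m.segments[-1] = (cur, m.segments[-1][1], mv - 1)
            m.segments.append((target, mv, None))
            if rng.random() < config.prospecting_arrival_prob:
                m.prospecting_arrivals.add(mv)
            last = mv
        # close at death / observation end
        g_last, s_last, _ = m.segments[-1]
        end = m.death if m.death is not None else obs1
        m.segments[-1] = (g_last, s_last, min(end, obs1))
        m.segments = [(g, s, e) for (g, s, e) in m.segments if e is None or e >= s]
        # prospecting excursions that do not change residence
        for year in season_years:
            if rng.random() < config.excursion_prob:
                seg = None
                day = _D(year, 7, 1).toordinal() + int(rng.integers(0, 200))
                for (g, s, e) in m.segments:
                    if s <= day and (e is None or day + 3 <= e):
                        seg = (g, s, e)
                        break
                if seg is None or day < seg[1] + 70:
                    continue
                nb = config.neighbors(seg[0])
                m.excursions.append((day, nb[int(rng.integers(0, len(nb)))]))
        individuals.append(Individual(
            m.id, MALE, from_ordinal(m.birth),
            from_ordinal(m.death) if m.death is not None else None,
            m.natal_group))

    sightings = _emit_sightings(config, males)
    seasons = pd.DataFrame(
        [(g, y, config.season_onset(y).isoformat(),
          config.season_end(y).isoformat())
         for g in groups for y in config.cohort_years],
        columns=["group", "cohort_year", "mating_onset", "mating_end"])
    return individuals, males, sightings, seasons


def _emit_sightings(config: SimConfig, males: Sequence[_Male]) -> pd.DataFrame:
    step = config.sighting_interval_days
    ids, days, grps, ctxs = [], [], [], []
    for m in males:
        excur = sorted(m.excursions)
        for (g, s, e) in m.segments:
            d = np.arange(s, (e if e is not None else s) + 1, step)
            ctx = np.full(len(d), "routine", dtype=object)
            if s in m.prospecting_arrivals:
                ctx[:2] = "prospecting"
            keep = np.ones(len(d), dtype=bool)
            for (x0, target) in excur:
                if s <= x0 and (e is None or x0 + 3 <= e):
                    keep &= (d < x0) | (d > x0 + 3)
            d, ctx = d[keep], ctx[keep]
            ids.append(np.full(len(d), m.id, dtype=object))
            days.append(d)
            grps.append(np.full(len(d), g, dtype=object))
            ctxs.append(ctx)
        for (x0, target) in excur:
            ids.append(np.full(2, m.id, dtype=object))
            days.append(np.array([x0, x0 + 3]))
            grps.append(np.full(2, target, dtype=object))
            ctxs.append(np.full(2, "prospecting", dtype=object))
    df = pd.DataFrame({
        "id": np.concatenate(ids),
        "_ord": np.concatenate(days),
        "group": np.concatenate(grps),
        "context": np.concatenate(ctxs),
    })
    df = df.sort_values(["id", "_ord"], kind="stable").reset_index(drop=True)
    epoch = _D(1970, 1, 1).toordinal()
    df["date"] = (df["_ord"] - epoch).to_numpy().astype("datetime64[D]")
    return df[["id", "date", "group", "context"]]


def truth_intervals(males: Sequence[_Male]) -> List[MembershipInterval]:
    out = []
    for m in males:
        for (g, s, e) in m.segments:
            out.append(MembershipInterval(
                m.id, g, from_ordinal(s),
                from_ordinal(e) if e is not None else None))
    return out


def _truth_covariates(config: SimConfig, individuals, males,
                      conceptions: pd.DataFrame) -> pd.DataFrame:
    """Group-season covariates computed on the generator's own truth."""
    index = MembershipIndex(individuals, truth_intervals(males))
    w = int(np.floor(2 * config.gestation_sd_days)) // 2  # 15-day window half
    rows = []
    for y in config.cohort_years:
        o0 = config.season_onset(y).toordinal()
        o1 = config.season_end(y).toordinal()
        for g in config.groups():
            n_f, n_m = index.daily_mature_counts(
                g, np.array([o0], dtype=np.int64))
            size = int(n_f[0] + n_m[0])
            ratio = float(n_f[0] / max(int(n_m[0]), 1))
            sel = conceptions[(conceptions["group"] == g)
                              & (conceptions["cohort"] == y)]
            days = set()
            for c in sel["conception_ord"]:
                days.update(range(int(c) - w, int(c) + w + 1))
            synchrony = (2 * w + 1) / len(days) if days else np.nan
            inst = group_instability(
                g, SeasonCalendar(g, y, from_ordinal(o0), from_ordinal(o1)),
                index).instability
            rows.append((g, y, size, ratio, synchrony, inst))
    return pd.DataFrame(rows, columns=["group", "cohort", "size", "sex_ratio",
                                       "synchrony", "instability"])


def simulate_matings(config: SimConfig, individuals, males,
                     rng: np.random.Generator):
    """Conceptions, sire choice under the extra-group model, and infant fates.

    Returns ``(adults, infants, births_df, parentage_df, covariates_df)``;
    ``adults`` is the input list with culling deaths applied.
    """
    females = [i for i in individuals if i.sex == FEMALE]
    index = MembershipIndex(individuals, truth_intervals(males))
    male_by_id = {m.id: m for m in males}
    sex_of = {i.id: i.sex for i in individuals}
    birth_of = {m.id: m.birth for m in males}

    conc_rows = []
    for y in config.cohort_years:
        o0 = config.season_onset(y).toordinal()
        for f in females:
            if f.natal_group is None:
                continue
            if o0 - f.birth_date.toordinal() <= 1250:
                continue
            if f.death_date is not None and f.death_date.toordinal() < o0:
                continue
            if rng.random() >= config.female_birth_prob:
                continue
            c = o0 + int(rng.integers(0, config.season_length_days))
            conc_rows.append((f.id, f.natal_group, y, c))
    conceptions = pd.DataFrame(
        conc_rows, columns=["mother", "group", "cohort", "conception_ord"])

    cov = _truth_covariates(config, individuals, males, conceptions)
    z = {}
    for colname in ("sex_ratio", "size", "synchrony", "instability"):
        x = cov[colname].to_numpy(dtype=float)
        mu, sd = np.nanmean(x), np.nanstd(x, ddof=1)
        z[colname] = (x - mu) / sd if sd > 0 else np.zeros_like(x)
    g0, g1, g2, g3, g4, g5 = config.egp_gamma
    logodds = (g0 + g1 * z["sex_ratio"] + g2 * z["size"] + g3 * z["synchrony"]
               + g4 * z["instability"] + g5 * z["sex_ratio"] * z["size"])
    p_egp = 1.0 / (1.0 + np.exp(-np.nan_to_num(logodds, nan=g0)))
    cov["p_egp"] = p_egp
    p_by_cell = {(r.group, r.cohort): r.p_egp
                 for r in cov.itertuples(index=False)}

    def mature_males_in(group, day):
        members = index.members_on_date(group, from_ordinal(day))
        return sorted(i for i in members
                      if sex_of.get(i) == MALE
                      and day - birth_of.get(i, day) > config.egp_min_sire_age_days)

    new_inds: List[Individual] = []
    births, parentage = [], []
    seq = 0
    for rec in conceptions.itertuples(index=False):
        c = int(rec.conception_ord)
        group = rec.group
        within = mature_males_in(group, c)
        extra = []
        for nb in config.neighbors(group):
            for mid in mature_males_in(nb, c):
                if index.membership_overlap_days(
                        mid, group, from_ordinal(c - 45),
                        from_ordinal(c + 45)) == 0:
                    extra.append(mid)
        want_egp = rng.random() < p_by_cell[(group, rec.cohort)]
        if want_egp and extra:
            sire = extra[int(rng.integers(0, len(extra)))]
            egp = True
        elif within:
            sire = within[int(rng.integers(0, len(within)))]
            egp = False
        elif extra:
            sire = extra[int(rng.integers(0, len(extra)))]
            egp = True
        else:
            continue  # no mature male anywhere nearby; conception dropped
        gest = int(round(rng.normal(config.gestation_mean_days,
                                    config.gestation_sd_days)))
        birth = c + gest
        oid = f"I-{rec.cohort}-{seq:04d}"
        seq += 1
        sex = MALE if rng.random() < 0.5 else FEMALE
        death = None
        if rng.random() < config.infant_death_prob:
            death = birth + int(rng.integers(0, 361))
        births.append((oid, rec.mother, from_ordinal(birth), group))
        parentage.append((oid, rec.mother, sire, from_ordinal(c), egp,
                          group, rec.cohort))
        new_inds.append(Individual(oid, sex, from_ordinal(birth),
                                   from_ordinal(death) if death else None,
                                   group))

    births_df = pd.DataFrame(
        births, columns=["offspring", "mother", "birth_date", "natal_group"])
    parentage_df = pd.DataFrame(
        parentage, columns=["offspring", "mother", "sire", "conception_date",
                            "egp", "group", "cohort"])

    # culling: a few infants leave the island together with their mother
    new_by_id = {i.id: i for i in new_inds}
    mother_last = births_df.groupby("mother")["birth_date"].transform("max")
    removable = births_df["birth_date"] == mother_last
    fem_by_id = {f.id: f for f in females}
    removed = rng.random(len(births_df)) < config.removed_with_mother_prob
    for k in np.flatnonzero(removed & removable.to_numpy()):
        row = births_df.iloc[k]
        inf = new_by_id[row.offspring]
        if inf.death_date is not None:
            continue
        when = from_ordinal(row.birth_date.toordinal()
                            + int(rng.integers(30, 331)))
        new_by_id[row.offspring] = Individual(inf.id, inf.sex, inf.birth_date,
                                              when, inf.natal_group)
        mom = fem_by_id[row.mother]
        fem_by_id[row.mother] = Individual(mom.id, mom.sex, mom.birth_date,
                                           when, mom.natal_group)
    # remaining survivors are culled as juveniles (population control)
    lo, hi = config.juvenile_cull_age_range
    for oid, inf in new_by_id.items():
        if inf.death_date is None:
            cull = inf.birth_date.toordinal() + int(rng.integers(lo, hi + 1))
            new_by_id[oid] = Individual(inf.id, inf.sex, inf.birth_date,
                                        from_ordinal(cull), inf.natal_group)
    new_inds = list(new_by_id.values())
    updated = [fem_by_id.get(i.id, i) for i in individuals]
    return updated, new_inds, births_df, parentage_df, cov


def simulate_genotypes(config: SimConfig, individuals: Sequence[Individual],
                       parentage: pd.DataFrame,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Founder draws + Mendelian descent + error + panel dropout, long format."""
    loci = [f"L{j + 1:02d}" for j in range(config.n_loci)]
    freqs = rng.dirichlet(np.full(config.n_alleles, config.dirichlet_alpha),
                          size=config.n_loci)
    parents = {r.offspring: (r.mother, r.sire)
               for r in parentage.itertuples(index=False)}
    ungenotyped = {r.offspring for r in parentage.itertuples(index=False)
                   if rng.random() < config.ungenotyped_prob}

    geno: Dict[str, np.ndarray] = {}

    def draw_founder() -> np.ndarray:
        g = np.empty((config.n_loci, 2), dtype=np.int32)
        for j in range(config.n_loci):
            g[j] = rng.choice(config.n_alleles, size=2, p=freqs[j]) + 1
        return g

    founders = [i for i in individuals if i.id not in parents]
    children = [i for i in individuals if i.id in parents]
    for ind in founders:
        geno[ind.id] = draw_founder()
    for ind in children:
        mom, dad = parents[ind.id]
        g = np.empty((config.n_loci, 2), dtype=np.int32)
        pick_m = rng.integers(0, 2, config.n_loci)
        pick_d = rng.integers(0, 2, config.n_loci)
        g[:, 0] = geno[mom][np.arange(config.n_loci), pick_m]
        g[:, 1] = geno[dad][np.arange(config.n_loci), pick_d]
        geno[ind.id] = g

    e = config.genotyping_error_rate
    rows = []
    for ind in individuals:
        if ind.id in ungenotyped:
            continue
        g = geno[ind.id].copy()
        if e > 0:
            err = rng.random(g.shape) < e
            for j, k in zip(*np.nonzero(err)):
                g[j, k] = rng.choice(config.n_alleles, p=freqs[j]) + 1
        n_typed = int(np.clip(round(rng.normal(config.panel_mean,
                                               config.panel_sd)),
                              config.panel_min, config.n_loci))
        keep = rng.permutation(config.n_loci)[:n_typed]
        for j in sorted(keep):
            rows.append((ind.id, loci[j], int(g[j, 0]), int(g[j, 1])))
    return pd.DataFrame(rows, columns=["id", "locus", "allele1", "allele2"])


def simulate_locations(config: SimConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Daily group centroids: Gaussian scatter around ring-arranged centers."""
    cx, cy = config.range_center_xy
    groups = config.groups()
    centers = {
        g: (cx + config.range_ring_radius * np.cos(2 * np.pi * i / len(groups)),
            cy + config.range_ring_radius * np.sin(2 * np.pi * i / len(groups)))
        for i, g in enumerate(groups)}
    epoch = _D(1970, 1, 1).toordinal()
    rows = []
    for y in config.cohort_years:
        o0 = config.season_onset(y).toordinal()
        days = np.arange(o0, o0 + config.season_length_days)
        for g in groups:
            x = rng.normal(centers[g][0], config.range_scatter_sd, len(days))
            yv = rng.normal(centers[g][1], config.range_scatter_sd, len(days))
            for d, xx, yy in zip(days, x, yv):
                rows.append((g, d, round(float(xx), 2), round(float(yy), 2)))
    df = pd.DataFrame(rows, columns=["group", "_ord", "x", "y"])
    df["date"] = (df["_ord"] - epoch).to_numpy().astype("datetime64[D]")
    return df[["group", "date", "x", "y"]]


def simulate_all(config: SimConfig) -> SimData:
    """Run every sub-generator off one fanned-out root seed."""
    ss = np.random.SeedSequence(config.seed)
    r_pop, r_mate, r_geno, r_loc = (np.random.default_rng(s)
                                    for s in ss.spawn(4))
    individuals, males, sightings, seasons = simulate_population(config, r_pop)
    individuals, infants, births, parentage, cov = simulate_matings(
        config, individuals, males, r_mate)
    everyone = individuals + infants
    genotypes = simulate_genotypes(config, everyone, parentage, r_geno)
    locations = simulate_locations(config, r_loc)

    census = pd.DataFrame(
        [(i.id, i.sex, i.birth_date.isoformat(),
          i.death_date.isoformat() if i.death_date else "", i.natal_group)
         for i in everyone],
        columns=["id", "sex", "birth_date", "death_date", "natal_group"])
    truth = TruthLog(parentage=parentage,
                     intervals=truth_intervals(males),
                     covariates=cov)
    return SimData(config=config, census=census, sightings=sightings,
                   seasons=seasons, births=births, genotypes=genotypes,
                   locations=locations, truth=truth)


def write_csvs(sim: SimData, outdir) -> Dict[str, str]:
    """Emit all input CSVs plus the truth tables; returns written paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _w(name, df):
        p = os.path.join(outdir, name)
        df.to_csv(p, index=False)
        paths[name] = p

    sights = sim.sightings.copy()
    sights["date"] = pd.to_datetime(sights["date"]).dt.strftime("%Y-%m-%d")
    locs = sim.locations.copy()
    locs["date"] = pd.to_datetime(locs["date"]).dt.strftime("%Y-%m-%d")
    births = sim.births.copy()
    births["birth_date"] = births["birth_date"].map(lambda d: d.isoformat())
    par = sim.truth.parentage.copy()
    par["conception_date"] = par["conception_date"].map(lambda d: d.isoformat())
    _w("census.csv", sim.census)
    _w("sightings.csv", sights)
    _w("seasons.csv", sim.seasons)
    _w("births.csv", births)
    _w("genotypes.csv", sim.genotypes)
    _w("locations.csv", locs)
    _w("truth.csv", par)
    _w("truth_covariates.csv", sim.truth.covariates)
    iv = pd.DataFrame(
        [(v.individual_id, v.group, v.start_date.isoformat(),
          v.end_date.isoformat() if v.end_date else "")
         for v in sim.truth.intervals],
        columns=["id", "group", "start_date", "end_date"])
    _w("truth_intervals.csv", iv)
    return paths
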