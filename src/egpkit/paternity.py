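"""Parentage assignment from microsatellite genotypes by locus exclusion.

Candidate sires are genotyped males old enough to breed and present when the
infant was conceived.  A candidate is Mendelian-consistent at a locus when
one offspring allele can come from the mother and the other is carried by
the candidate.  Assignment rules:

* ``strict``       – assigned sire has 0 mismatches, every other candidate is
  excluded at >= 2 loci;
* ``relaxed``      – assigned sire has 0 mismatches, the closest other
  candidate is excluded at exactly 1 locus;
* ``one_mismatch`` – assigned sire has exactly 1 mismatch, all other
  candidates are excluded at >= 2 loci;
* ``unassigned``   – anything else (ties are never broken).

Loci at which the offspring shares no allele with the mother are attributed
to maternity (genotyping error or misassigned mother), flagged, and skipped
when counting sire exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._dates import ordinal
from .demography import MALE, Individual

MISSING = -1

STRICT = "strict"
RELAXED = "relaxed"
ONE_MISMATCH = "one_mismatch"
UNASSIGNED = "unassigned"


class GenotypeTable:
    """Individuals x microsatellite loci, two unordered alleles per locus.

    Backed by an int array of shape ``(n_individuals, n_loci, 2)`` with
    ``-1`` marking untyped loci.  Built from a long-format table
    ``id, locus, allele1, allele2`` (allele codes are positive integers).
    """

    def __init__(self, alleles: np.ndarray, ids: Sequence[str],
                 loci: Sequence[str]):
        alleles = np.asarray(alleles, dtype=np.int32)
        if alleles.ndim != 3 or alleles.shape[2] != 2:
            raise ValueError("allele array must have shape (n, L, 2)")
        self.alleles = alleles
        self.ids = list(ids)
        self.loci = list(loci)
        self._row = {i: k for k, i in enumerate(self.ids)}
        if (alleles[alleles != MISSING] <= 0).any():
            raise ValueError("allele codes must be positive integers")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "GenotypeTable":
        loci = sorted(df["locus"].unique())
        ids = list(pd.unique(df["id"]))
        locus_ix = {l: j for j, l in enumerate(loci)}
        row_ix = {i: k for k, i in enumerate(ids)}
        arr = np.full((len(ids), len(loci), 2), MISSING, dtype=np.int32)
        r = df["id"].map(row_ix).to_numpy()
        c = df["locus"].map(locus_ix).to_numpy()
        arr[r, c, 0] = df["allele1"].to_numpy()
        arr[r, c, 1] = df["allele2"].to_numpy()
        return cls(arr, ids, loci)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, ind in enumerate(self.ids):
            typed = np.flatnonzero(self.alleles[i, :, 0] != MISSING)
            for j in typed:
                rows.append((ind, self.loci[j],
                             int(self.alleles[i, j, 0]),
                             int(self.alleles[i, j, 1])))
        return pd.DataFrame(rows, columns=["id", "locus", "allele1", "allele2"])

    def __contains__(self, individual_id) -> bool:
        return individual_id in self._row

    def row(self, individual_id) -> int:
        try:
            return self._row[individual_id]
        except KeyError:
            raise KeyError(f"{individual_id!r} is not genotyped") from None

    def genotype(self, individual_id) -> np.ndarray:
        """(L, 2) allele array for one individual (-1 = untyped)."""
        return self.alleles[self.row(individual_id)]

    def typed_mask(self, individual_id) -> np.ndarray:
        return self.genotype(individual_id)[:, 0] != MISSING

    def n_typed(self, individual_id) -> int:
        return int(self.typed_mask(individual_id).sum())


@dataclass(frozen=True)
class PaternityParams:
    """Candidate-sire criteria and exclusion-rule constants."""

    min_sire_age_days: int = 1250
    presence_before_birth_days: int = 200
    strict_exclusion_min_loci: int = 2
    min_joint_loci: int = 13  # half the mean marker panel
    maternity_max_mismatch: int = 0

    def __post_init__(self):
        if min(self.min_sire_age_days, self.presence_before_birth_days,
               self.strict_exclusion_min_loci, self.min_joint_loci) <= 0:
            raise ValueError("paternity parameters must be positive")


@dataclass
class PaternityAssignment:
    offspring_id: str
    sire_id: Optional[str]
    rule: str
    mismatch_count: Optional[int]
    candidate_mismatches: dict = field(default_factory=dict)
    n_candidates: int = 0
    reason: Optional[str] = None


def _consistency(off: np.ndarray, mom: np.ndarray, cand: np.ndarray):
    """Per-locus Mendelian bookkeeping for candidate array (..., L, 2).

    Returns (joint_typed, maternal_ok, paternal_ok) boolean arrays of shape
    (..., L) broadcast over leading candidate axes.
    """
    o1, o2 = off[:, 0], off[:, 1]
    s1 = (o1 == mom[:, 0]) | (o1 == mom[:, 1])
    s2 = (o2 == mom[:, 0]) | (o2 == mom[:, 1])
    t1 = (o1 == cand[..., 0]) | (o1 == cand[..., 1])
    t2 = (o2 == cand[..., 0]) | (o2 == cand[..., 1])
    typed = ((off[:, 0] != MISSING) & (mom[:, 0] != MISSING)
             & (cand[..., 0] != MISSING))
    maternal_ok = s1 | s2
    paternal_ok = (s1 & t2) | (s2 & t1)
    return typed, maternal_ok, paternal_ok


def trio_mismatch_count(offspring, mother, candidate,
                        genotypes: GenotypeTable) -> int:
    """Number of jointly typed loci at which the candidate is excluded.

    Loci where the offspring shares no allele with the mother are counted as
    maternal mismatches and skipped for the sire count.  Raises if the trio
    shares no typed locus.
    """
    off = genotypes.genotype(offspring)
    mom = genotypes.genotype(mother)
    cand = genotypes.genotype(candidate)
    typed, maternal_ok, paternal_ok = _consistency(off, mom, cand)
    if not typed.any():
        raise ValueError(
            f"trio ({offspring}, {mother}, {candidate}) shares no typed locus"
        )
    return int((typed & maternal_ok & ~paternal_ok).sum())


def maternal_mismatch_loci(offspring, mother, genotypes: GenotypeTable) -> int:
    """Jointly typed loci at which mother and offspring share no allele."""
    off = genotypes.genotype(offspring)
    mom = genotypes.genotype(mother)
    typed = (off[:, 0] != MISSING) & (mom[:, 0] != MISSING)
    s1 = (off[:, 0] == mom[:, 0]) | (off[:, 0] == mom[:, 1])
    s2 = (off[:, 1] == mom[:, 0]) | (off[:, 1] == mom[:, 1])
    return int((typed & ~(s1 | s2)).sum())


def confirm_maternity(offspring, mother, genotypes: GenotypeTable,
                      max_mismatch: int = 0) -> str:
    """``"confirmed"`` iff the mother shares an allele with the offspring at
    every jointly typed locus (up to ``max_mismatch`` conflicting loci)."""
    n_bad = maternal_mismatch_loci(offspring, mother, genotypes)
    return "confirmed" if n_bad <= max_mismatch else "mismatched"


def candidate_sires(offspring: Individual | str, birth_date,
                    individuals: Iterable[Individual],
                    genotypes: GenotypeTable,
                    params: PaternityParams = PaternityParams()) -> set:
    """Genotyped males old enough and present when the infant was conceived.

    A male qualifies if his age exceeds ``min_sire_age_days`` and he was
    alive ``presence_before_birth_days`` before the infant's birth (the
    conservative bound on the conception date).
    """
    ref = ordinal(birth_date) - params.presence_before_birth_days
    oid = offspring.id if isinstance(offspring, Individual) else offspring
    out = set()
    for ind in individuals:
        if ind.sex != MALE or ind.id == oid or ind.id not in genotypes:
            continue
        if ref - ind.birth_date.toordinal() <= params.min_sire_age_days:
            continue
        if ind.death_date is not None and ind.death_date.toordinal() < ref:
            continue
        out.add(ind.id)
    return out


def mismatch_vector(offspring, mother, candidates: Sequence[str],
                    genotypes: GenotypeTable):
    """Vectorized exclusion counts for many candidates at once.

    Returns ``(mismatches, joint_loci)`` integer arrays aligned with
    ``candidates``.
    """
    off = genotypes.genotype(offspring)
    mom = genotypes.genotype(mother)
    rows = np.array([genotypes.row(c) for c in candidates], dtype=np.intp)
    cand = genotypes.alleles[rows]  # (K, L, 2)
    typed, maternal_ok, paternal_ok = _consistency(off, mom, cand)
    countable = typed & maternal_ok
    mism = (countable & ~paternal_ok).sum(axis=-1)
    return mism.astype(np.int64), typed.sum(axis=-1).astype(np.int64)


def assign_paternity(offspring, mother, candidates, genotypes: GenotypeTable,
                     params: PaternityParams = PaternityParams()
                     ) -> PaternityAssignment:
    """Assign a sire by the exclusion rules; never assign on ties."""
    candidates = sorted(candidates)
    if not candidates:
        return PaternityAssignment(offspring, None, UNASSIGNED, None,
                                   reason="no_candidates")
    mism, joint = mismatch_vector(offspring, mother, candidates, genotypes)
    usable = joint >= params.min_joint_loci
    if not usable.any():
        return PaternityAssignment(
            offspring, None, UNASSIGNED, None,
            candidate_mismatches=dict(zip(candidates, map(int, mism))),
            n_candidates=len(candidates), reason="insufficient_joint_loci")
    cand = [c for c, u in zip(candidates, usable) if u]
    mm = mism[usable]
    per_cand = dict(zip(cand, map(int, mm)))
    best, rule, best_mm, reason = _classify(mm, params)
    sire = cand[best] if best is not None else None
    return PaternityAssignment(offspring, sire, rule, best_mm, per_cand,
                               len(candidates), reason=reason)


def _classify(mm: np.ndarray, params: PaternityParams):
    """Rule classification for an exclusion-count vector.

    Returns ``(best_index, rule, best_mm, reason)``; ``best_index`` is None
    when unassigned.
    """
    best = int(np.argmin(mm))
    best_mm = int(mm[best])
    if best_mm > 1:
        return None, UNASSIGNED, None, "no_compatible_male"
    if int((mm == best_mm).sum()) > 1:
        return None, UNASSIGNED, None, f"tie_at_{best_mm}_mismatches"
    others = np.delete(mm, best)
    other_min = int(others.min()) if len(others) else params.strict_exclusion_min_loci
    if best_mm == 0:
        rule = (STRICT if other_min >= params.strict_exclusion_min_loci
                else RELAXED)
        return best, rule, 0, None
    if other_min < params.strict_exclusion_min_loci:
        return None, UNASSIGNED, None, "one_mismatch_not_unique"
    return best, ONE_MISMATCH, 1, None


def assign_all(births: pd.DataFrame, individuals: Iterable[Individual],
               genotypes: GenotypeTable,
               params: PaternityParams = PaternityParams()) -> pd.DataFrame:
    """Assign paternity for every offspring row (``offspring, mother,
    birth_date, natal_group``); maternity is genetically confirmed first.

    Returns a DataFrame ``offspring, sire, rule, mismatches, n_candidates,
    reason``.
    """
    males = [i for i in individuals if i.sex == MALE and i.id in genotypes]
    m_ids = np.array([i.id for i in males], dtype=object)
    m_birth = np.array([i.birth_date.toordinal() for i in males], dtype=np.int64)
    m_death = np.array(
        [i.death_date.toordinal() if i.death_date else np.iinfo(np.int64).max // 2
         for i in males], dtype=np.int64)
    m_rows = np.array([genotypes.row(i) for i in m_ids], dtype=np.intp)

    rows = []
    for rec in births.itertuples(index=False):
        oid, mid = rec.offspring, rec.mother
        if oid not in genotypes or mid not in genotypes:
            rows.append((oid, None, UNASSIGNED, None, 0, "missing_genotype"))
            continue
        if confirm_maternity(oid, mid, genotypes,
                             params.maternity_max_mismatch) != "confirmed":
            rows.append((oid, None, UNASSIGNED, None, 0, "maternity_unconfirmed"))
            continue
        ref = ordinal(rec.birth_date) - params.presence_before_birth_days
        ok = ((ref - m_birth > params.min_sire_age_days)
              & (m_death >= ref) & (m_ids != oid))
        n_cand = int(ok.sum())
        if n_cand == 0:
            rows.append((oid, None, UNASSIGNED, None, 0, "no_candidates"))
            continue
        off = genotypes.genotype(oid)
        mom = genotypes.genotype(mid)
        cand = genotypes.alleles[m_rows[ok]]
        typed, maternal_ok, paternal_ok = _consistency(off, mom, cand)
        joint = typed.sum(axis=-1)
        usable = joint >= params.min_joint_loci
        if not usable.any():
            rows.append((oid, None, UNASSIGNED, None, n_cand,
                         "insufficient_joint_loci"))
            continue
        mm = ((typed & maternal_ok & ~paternal_ok).sum(axis=-1))[usable]
        ids = m_ids[ok][usable]
        best, rule, best_mm, reason = _classify(mm, params)
        sire = ids[best] if best is not None else None
        rows.append((oid, sire, rule, best_mm, n_cand, reason))
    return pd.DataFrame(
        rows, columns=["offspring", "sire", "rule", "mismatches",
                       "n_candidates", "reason"])
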