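"""Readers and writers for the pipeline's CSV interfaces.

Every reader validates the header bit-exactly before parsing, so a
mis-shapen input fails at the door with the offending file named rather
than deep inside a stage.  Dates are ISO-8601 throughout.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from ._dates import as_date
from .demography import Individual, SeasonCalendar

CENSUS_HEADER = ["id", "sex", "birth_date", "death_date", "natal_group"]
SIGHTINGS_HEADER = ["id", "date", "group", "context"]
SEASONS_HEADER = ["group", "cohort_year", "mating_onset", "mating_end"]
GENOTYPES_HEADER = ["id", "locus", "allele1", "allele2"]
BIRTHS_HEADER = ["offspring", "mother", "birth_date", "natal_group"]
LOCATIONS_HEADER = ["group", "date", "x", "y"]


def _check_header(path, expected: Sequence[str]) -> None:
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    if header != list(expected):
        raise ValueError(
            f"{path}: header {header!r} does not match required "
            f"{list(expected)!r}")


def read_census(path) -> List[Individual]:
    _check_header(path, CENSUS_HEADER)
    df = pd.read_csv(path, dtype={"id": str, "natal_group": str},
                     keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        death = r.death_date or None
        out.append(Individual(r.id, r.sex, as_date(r.birth_date),
                              as_date(death) if death else None,
                              r.natal_group or None))
    return out


def read_sightings(path) -> pd.DataFrame:
    _check_header(path, SIGHTINGS_HEADER)
    df = pd.read_csv(path, dtype={"id": str, "group": str, "context": str})
    df["date"] = pd.to_datetime(df["date"]).to_numpy().astype("datetime64[D]")
    return df


def read_seasons(path) -> List[SeasonCalendar]:
    _check_header(path, SEASONS_HEADER)
    df = pd.read_csv(path, dtype={"group": str})
    return [SeasonCalendar(r.group, int(r.cohort_year),
                           as_date(r.mating_onset), as_date(r.mating_end))
            for r in df.itertuples(index=False)]


def read_genotypes(path) -> pd.DataFrame:
    _check_header(path, GENOTYPES_HEADER)
    return pd.read_csv(path, dtype={"id": str, "locus": str,
                                    "allele1": int, "allele2": int})


def read_births(path) -> pd.DataFrame:
    _check_header(path, BIRTHS_HEADER)
    df = pd.read_csv(path, dtype={"offspring": str, "mother": str,
                                  "natal_group": str})
    df["birth_date"] = df["birth_date"].map(as_date)
    return df


def read_locations(path) -> pd.DataFrame:
    _check_header(path, LOCATIONS_HEADER)
    df = pd.read_csv(path, dtype={"group": str})
    df["date"] = pd.to_datetime(df["date"]).to_numpy().astype("datetime64[D]")
    return df
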