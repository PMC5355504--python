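"""Calendar-date helpers.

All computations inside the package run on proleptic Gregorian ordinals
(``datetime.date.toordinal``) so that day arithmetic is plain integer
arithmetic.  Public functions accept ``datetime.date`` objects or ISO-8601
strings; DataFrame columns may additionally hold numpy ``datetime64`` values.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

#: proleptic ordinal of 1970-01-01, the numpy datetime64 epoch
EPOCH_ORDINAL = _dt.date(1970, 1, 1).toordinal()


def as_date(value) -> _dt.date:
    """Coerce a scalar to a ``datetime.date``."""
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    if isinstance(value, str):
        return _dt.date.fromisoformat(value)
    if isinstance(value, np.datetime64):
        days = value.astype("datetime64[D]").astype(int)
        return _dt.date.fromordinal(int(days) + EPOCH_ORDINAL)
    if isinstance(value, pd.Timestamp):
        return value.date()
    raise TypeError(f"cannot interpret {value!r} as a calendar date")


def ordinal(value) -> int:
    """Proleptic ordinal of a scalar date-like value."""
    return as_date(value).toordinal()


def from_ordinal(o: int) -> _dt.date:
    return _dt.date.fromordinal(int(o))


def to_ordinals(values) -> np.ndarray:
    """Vectorized conversion of a date-like column to int64 ordinals."""
    arr = np.asarray(values)
    if np.issubdtype(arr.dtype, np.datetime64):
        return arr.astype("datetime64[D]").astype(np.int64) + EPOCH_ORDINAL
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.int64)
    # object arrays of dates / strings
    return np.array([ordinal(v) for v in values], dtype=np.int64)
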