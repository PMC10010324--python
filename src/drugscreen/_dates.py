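"""Calendar helpers.

All internal computation uses integer days since 1970-01-01; the public
DataFrames carry pandas datetime64 columns and CSV files carry ISO-8601
strings. Calendar-year shifts are anniversary-based; a Feb 29 anniversary
maps to Feb 28.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["to_days", "series_to_days", "days_to_datetime", "shift_years",
           "shift_years_scalar", "year_of"]


def to_days(x) -> int:
    """Convert a date-like scalar (str, date, Timestamp) to days since epoch."""
    return (pd.Timestamp(x) - pd.Timestamp(0)).days


def series_to_days(s: pd.Series) -> np.ndarray:
    """Convert a datetime-like Series to int64 days since epoch."""
    return pd.to_datetime(s).values.astype("datetime64[D]").astype("int64")


def days_to_datetime(days) -> pd.Series:
    """Convert int days since epoch back to a datetime64[ns] Series."""
    return pd.Series(pd.to_datetime(np.asarray(days, dtype="int64"), unit="D"))


def shift_years(days, years: int) -> np.ndarray:
    """Shift each date by a whole number of calendar years (vectorized)."""
    arr = np.asarray(days, dtype="int64")
    ts = pd.DatetimeIndex(pd.to_datetime(arr, unit="D"))
    y = ts.year.to_numpy() + years
    m = ts.month.to_numpy()
    d = ts.day.to_numpy()
    d = np.where((m == 2) & (d == 29), 28, d)
    out = pd.to_datetime(pd.DataFrame({"year": y, "month": m, "day": d}))
    return out.values.astype("datetime64[D]").astype("int64")


def shift_years_scalar(day: int, years: int) -> int:
    return int(shift_years(np.array([day]), years)[0])


def year_of(days) -> np.ndarray:
    """Calendar year of each date given as int days since epoch."""
    arr = np.asarray(days, dtype="int64")
    return pd.DatetimeIndex(pd.to_datetime(arr, unit="D")).year.to_numpy()
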