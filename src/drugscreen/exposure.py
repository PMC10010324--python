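"""Per-subject exposure and covariates for one drug-cancer pair.

Exposure is the cumulative number of filled prescriptions of the target
drug (exact ATC level-5 code, or level-4 prefix in class mode) inside the
half-open window [registry_start, index_date - lag_years); the default
two-year lag discards recent use to blunt protopathic and surveillance
bias. Counts are categorized as nonuse (0), low (1-2), intermediate (3-7)
and high (8+); the dose-response parametrization carries an ever-use
indicator plus log2 of the count, so one unit of the slope is one doubling
of cumulative use among ever-users.

Covariates (Charlson comorbidity score and education) share the identical
window end. The Charlson map is a swappable package data file with the two
malignancy entities removed, since subjects with prior cancer are excluded
by design.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from ._dates import series_to_days, shift_years, to_days
from .errors import ConfigError
from .registry import EDUCATION_LEVELS

CATEGORIES = ("nonuse", "low", "intermediate", "high")
_SELECTOR_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}(\d{2})?$")

_charlson_cache: pd.DataFrame | None = None


@dataclass(frozen=True)
class ExposureWindow:
    """Half-open assessment window [window_start, window_end), in days."""
    window_start: int
    window_end: int
    lag_years: int = 2

    @classmethod
    def from_index_date(cls, index_date, lag_years: int = 2,
                        registry_start="1995-01-01") -> "ExposureWindow":
        if lag_years < 0:
            raise ConfigError("lag_years", "must be >= 0")
        end = int(shift_years(np.array([to_days(index_date)]), -lag_years)[0])
        return cls(window_start=to_days(registry_start), window_end=end,
                   lag_years=lag_years)


def categorize_exposure(n_fills: int) -> str:
    """0 -> nonuse; 1-2 -> low; 3-7 -> intermediate; >=8 -> high."""
    if n_fills < 0:
        raise ValueError("n_fills must be >= 0")
    if n_fills == 0:
        return "nonuse"
    if n_fills <= 2:
        return "low"
    if n_fills <= 7:
        return "intermediate"
    return "high"


def categorize_exposure_array(n_fills: np.ndarray) -> np.ndarray:
    n = np.asarray(n_fills)
    if (n < 0).any():
        raise ValueError("n_fills must be >= 0")
    return np.select([n == 0, n <= 2, n <= 7],
                     ["nonuse", "low", "intermediate"], default="high")


def dose_response_terms(n_fills: int) -> tuple[int, float]:
    """(ever_use, log2_fills): (0, 0) for never-users, else (1, log2 n)."""
    if n_fills < 0:
        raise ValueError("n_fills must be >= 0")
    if n_fills == 0:
        return 0, 0.0
    return 1, float(np.log2(n_fills))


def _check_selector(atc_selector: str) -> None:
    if not _SELECTOR_RE.match(atc_selector):
        raise ValueError(f"malformed ATC selector {atc_selector!r}: need a "
                         "7-char level-5 code or 5-char level-4 prefix")


def _atc_mask(atc: pd.Series, selector: str) -> np.ndarray:
    if len(selector) == 7:
        return (atc == selector).to_numpy()
    return atc.str.startswith(selector).to_numpy()


def count_fills(prescriptions: pd.DataFrame, person_id: str, atc_selector: str,
                window: ExposureWindow) -> int:
    """Fills of the selected drug for one person within the window."""
    _check_selector(atc_selector)
    rx = prescriptions[prescriptions["person_id"] == person_id]
    if rx.empty:
        return 0
    m = _atc_mask(rx["atc"], atc_selector)
    day = series_to_days(rx["fill_date"])
    return int(((day >= window.window_start) & (day < window.window_end) & m).sum())


def count_fills_bulk(prescriptions: pd.DataFrame, subjects: pd.DataFrame,
                     atc_selector: str, window_start: int) -> np.ndarray:
    """Vectorized fill counts for many subjects.

    ``subjects`` needs columns person_id and _window_end (int days); one
    output element per subject row, aligned by position.
    """
    _check_selector(atc_selector)
    out = np.zeros(len(subjects), dtype=np.int64)
    if prescriptions.empty:
        return out
    rx = prescriptions[_atc_mask(prescriptions["atc"], atc_selector)]
    if rx.empty:
        return out
    rx = pd.DataFrame({"person_id": rx["person_id"],
                       "_day": series_to_days(rx["fill_date"])})
    rx = rx[rx["_day"] >= window_start]
    sub = subjects[["person_id", "_window_end"]].reset_index(drop=True)
    sub["_row"] = np.arange(len(sub))
    merged = sub.merge(rx, on="person_id", how="inner")
    if merged.empty:
        return out
    hits = merged[merged["_day"] < merged["_window_end"]]
    counts = hits.groupby("_row").size()
    out[counts.index.to_numpy()] = counts.to_numpy()
    return out


def load_charlson_map() -> pd.DataFrame:
    """Default ICD-10 prefix -> (entity, weight) map, malignancies excluded."""
    global _charlson_cache
    if _charlson_cache is None:
        with resources.files("drugscreen.data").joinpath(
                "charlson_icd10.csv").open() as fh:
            _charlson_cache = pd.read_csv(fh, dtype={"icd10_prefix": str,
                                                     "entity": str,
                                                     "weight": int})
    return _charlson_cache.copy()


def _map_entities(codes: pd.Series, code_map: pd.DataFrame):
    """Longest-prefix match of ICD-10 codes against the map (4 then 3 chars)."""
    ent_lut = pd.Series(code_map["entity"].to_numpy(),
                        index=code_map["icd10_prefix"])
    wt_lut = pd.Series(code_map["weight"].to_numpy(),
                       index=code_map["icd10_prefix"])
    clean = codes.str.upper().str.replace(".", "", regex=False).reset_index(drop=True)
    ent4 = clean.str[:4].map(ent_lut)
    ent3 = clean.str[:3].map(ent_lut)
    wt4 = clean.str[:4].map(wt_lut)
    wt3 = clean.str[:3].map(wt_lut)
    ent = ent4.where(ent4.notna(), ent3)
    wt = wt4.where(wt4.notna(), wt3).fillna(0).astype(np.int64)
    return ent.to_numpy(), wt.to_numpy()


def compute_cci(hospital_dx: pd.DataFrame, person_id: str,
                window: ExposureWindow,
                code_map: pd.DataFrame | None = None) -> int:
    """Charlson summary score from diagnoses dated before the window end.

    Each entity counts at most once regardless of how many qualifying
    diagnoses the person has.
    """
    if code_map is None:
        code_map = load_charlson_map()
    dx = hospital_dx[hospital_dx["person_id"] == person_id]
    if dx.empty:
        return 0
    day = series_to_days(dx["dx_date"])
    dx = dx[(day >= window.window_start) & (day < window.window_end)]
    if dx.empty:
        return 0
    ent, wt = _map_entities(dx["icd10"], code_map)
    seen = pd.DataFrame({"entity": ent, "weight": wt})
    seen = seen[seen["entity"].notna()].drop_duplicates("entity")
    return int(seen["weight"].sum())


def compute_cci_bulk(hospital_dx: pd.DataFrame, subjects: pd.DataFrame,
                     window_start: int,
                     code_map: pd.DataFrame | None = None) -> np.ndarray:
    """Charlson scores for many subjects (columns person_id, _window_end)."""
    if code_map is None:
        code_map = load_charlson_map()
    out = np.zeros(len(subjects), dtype=np.int64)
    if hospital_dx.empty:
        return out
    ent, wt = _map_entities(hospital_dx["icd10"], code_map)
    dx = pd.DataFrame({"person_id": hospital_dx["person_id"],
                       "_day": series_to_days(hospital_dx["dx_date"]),
                       "entity": ent, "weight": wt})
    dx = dx[dx["entity"].notna() & (dx["_day"] >= window_start)]
    if dx.empty:
        return out
    sub = subjects[["person_id", "_window_end"]].reset_index(drop=True)
    sub["_row"] = np.arange(len(sub))
    merged = sub.merge(dx, on="person_id", how="inner")
    merged = merged[merged["_day"] < merged["_window_end"]]
    if merged.empty:
        return out
    uniq = merged.drop_duplicates(["_row", "entity"])
    sums = uniq.groupby("_row")["weight"].sum()
    out[sums.index.to_numpy()] = sums.to_numpy()
    return out


# Keys combine a person position and a day as pos*KEYSCALE + day; days since
# 1970 stay far below KEYSCALE through the 3rd millennium.
_KEYSCALE = 2 ** 20


class PreparedContext:
    """Event tables indexed once for repeated per-pair exposure queries.

    Prescriptions are grouped by ATC code into sorted (person, day) keys and
    hospital diagnoses are Charlson-mapped and deduplicated to the earliest
    record per (person, entity), so that per-subject window counts reduce to
    binary searches. Shared by every pair in a screen run.
    """

    def __init__(self, persons: pd.DataFrame, prescriptions: pd.DataFrame,
                 hospital_dx: pd.DataFrame, *, registry_start="1995-01-01",
                 code_map: pd.DataFrame | None = None):
        self.window_start = to_days(registry_start)
        self.pid_index = pd.Series(np.arange(len(persons)),
                                   index=persons["person_id"])
        self.education = persons["education"].to_numpy()

        self._rx: dict[str, np.ndarray] = {}
        if not prescriptions.empty:
            ppos = prescriptions["person_id"].map(self.pid_index).to_numpy()
            day = series_to_days(prescriptions["fill_date"])
            keep = day >= self.window_start
            df = pd.DataFrame({"atc": prescriptions["atc"].to_numpy()[keep],
                               "key": ppos[keep] * _KEYSCALE + day[keep]})
            for a, g in df.groupby("atc", sort=True):
                self._rx[a] = np.sort(g["key"].to_numpy())
        self._selector_cache: dict[str, np.ndarray] = {}

        if code_map is None:
            code_map = load_charlson_map()
        if hospital_dx.empty:
            self._cci_key = np.empty(0, np.int64)
            self._cci_csum = np.zeros(1, np.int64)
        else:
            ent, wt = _map_entities(hospital_dx["icd10"], code_map)
            m = pd.DataFrame({
                "p": hospital_dx["person_id"].map(self.pid_index).to_numpy(),
                "e": ent, "w": wt,
                "d": series_to_days(hospital_dx["dx_date"])})
            m = m[pd.notna(m["e"]) & (m["d"] >= self.window_start)]
            first = (m.sort_values(["p", "e", "d"], kind="stable")
                     .drop_duplicates(["p", "e"]))
            key = (first["p"].to_numpy(np.int64) * _KEYSCALE
                   + first["d"].to_numpy(np.int64))
            order = np.argsort(key)
            self._cci_key = key[order]
            self._cci_csum = np.concatenate(
                ([0], np.cumsum(first["w"].to_numpy(np.int64)[order])))

    def _keys_for(self, selector: str) -> np.ndarray:
        _check_selector(selector)
        if selector not in self._selector_cache:
            if len(selector) == 7:
                arr = self._rx.get(selector, np.empty(0, np.int64))
            else:
                parts = [v for a, v in self._rx.items()
                         if a.startswith(selector)]
                arr = (np.sort(np.concatenate(parts)) if parts
                       else np.empty(0, np.int64))
            self._selector_cache[selector] = arr
        return self._selector_cache[selector]

    def atc_selectors(self, atc_level: int) -> list[str]:
        if atc_level == 5:
            return sorted(self._rx)
        return sorted({a[:5] for a in self._rx})

    def fills(self, ppos: np.ndarray, window_end: np.ndarray,
              selector: str) -> np.ndarray:
        """Fill counts in [registry_start, window_end) per subject row."""
        k = self._keys_for(selector)
        base = ppos.astype(np.int64) * _KEYSCALE
        return (np.searchsorted(k, base + window_end)
                - np.searchsorted(k, base)).astype(np.int64)

    def cci(self, ppos: np.ndarray, window_end: np.ndarray) -> np.ndarray:
        """Charlson scores with diagnoses dated before window_end."""
        base = ppos.astype(np.int64) * _KEYSCALE
        hi = np.searchsorted(self._cci_key, base + window_end)
        lo = np.searchsorted(self._cci_key, base)
        return self._cci_csum[hi] - self._cci_csum[lo]


def build_design(matched_sets: pd.DataFrame, persons: pd.DataFrame,
                 prescriptions: pd.DataFrame, hospital_dx: pd.DataFrame,
                 atc_selector: str, *, lag_years: int = 2,
                 registry_start="1995-01-01",
                 code_map: pd.DataFrame | None = None,
                 prepared: PreparedContext | None = None) -> pd.DataFrame:
    """Design matrix rows for one drug-cancer pair.

    One row per (set_id, person_id) with columns: set_id, person_id,
    is_case, n_fills, category, ever_use, log2_fills, cci, education.
    Exposure and covariates share the same per-subject window end
    (index_date minus lag_years, calendar shift). Pass a
    :class:`PreparedContext` to amortize event indexing across many pairs.
    """
    _check_selector(atc_selector)
    if lag_years < 0:
        raise ConfigError("lag_years", "must be >= 0")
    if prepared is None:
        prepared = PreparedContext(persons, prescriptions, hospital_dx,
                                   registry_start=registry_start,
                                   code_map=code_map)
    sub = matched_sets.reset_index(drop=True)
    wend = shift_years(series_to_days(sub["index_date"]), -lag_years)
    ppos = sub["person_id"].map(prepared.pid_index)
    if ppos.isna().any():
        missing = sub["person_id"][ppos.isna()].iloc[0]
        raise ConfigError("matched_sets", f"unknown person_id {missing!r}")
    ppos = ppos.to_numpy(np.int64)
    n_fills = prepared.fills(ppos, wend, atc_selector)
    cci = prepared.cci(ppos, wend)
    edu = prepared.education[ppos]
    ever = (n_fills >= 1).astype(int)
    log2f = np.where(n_fills >= 1, np.log2(np.maximum(n_fills, 1)), 0.0)
    return pd.DataFrame({
        "set_id": sub["set_id"],
        "person_id": sub["person_id"],
        "is_case": (sub["role"] == "case").astype(int),
        "n_fills": n_fills,
        "category": pd.Categorical(categorize_exposure_array(n_fills),
                                   categories=list(CATEGORIES)),
        "ever_use": ever,
        "log2_fills": log2f,
        "cci": cci,
        "education": pd.Categorical(edu, categories=list(EDUCATION_LEVELS)),
    })
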