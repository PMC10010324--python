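"""All-pairs drug-cancer screen with the two-stage signal cascade.

The screen enumerates every (drug selector, cancer outcome) pair with at
least ``min_exposed_cases`` (default 25) high-use cases — the bottleneck
rule: with fewer exposed cases even a perfectly null estimate cannot be
precise, the analytic best case with 25 exposed cases and 10 controls per
case being a 95% CI of roughly 0.7 to 1.5. Each surviving pair is fitted
with the categorical and the dose-response conditional logistic models,
then filtered by the cascade:

  stage 1: lower 95% confidence limit of the high-use OR above 1.25;
  stage 2: additionally, lower limit of the per-doubling OR above 1.

Comparisons are strict. Low-use neutrality (the low-use CI containing 1)
is reported as an annotation, not a filter. No multiple-testing correction
is applied; the expected count of chance-positive associations at a given
alpha is reported alongside instead.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dates import series_to_days, shift_years, to_days
from .clr import FitResult, fit_categorical_model, fit_dose_response_model
from .errors import ConfigError, FitError
from .exposure import PreparedContext, build_design, count_fills_bulk
from .registry import EventTables

Z95 = 1.959963984540054


@dataclass
class ScreenConfig:
    lag_years: int = 2
    registry_start: str = "1995-01-01"
    min_exposed_cases: int = 25
    high_threshold: float = 1.25
    atc_level: int = 5
    outcome_levels: tuple[str, ...] = ("histology", "site")

    def validate(self) -> None:
        if self.lag_years < 0:
            raise ConfigError("lag_years", "must be >= 0")
        if self.min_exposed_cases < 0:
            raise ConfigError("min_exposed_cases", "must be >= 0")
        if self.high_threshold <= 0:
            raise ConfigError("high_threshold", "must be > 0")
        if self.atc_level not in (4, 5):
            raise ConfigError("atc_level", "must be 4 or 5")
        if not set(self.outcome_levels) <= {"histology", "site"}:
            raise ConfigError("outcome_levels",
                              "entries must be 'histology' or 'site'")


@dataclass
class PairSpec:
    """One enumerated drug-cancer pair, pre-screened by the bottleneck rule."""
    atc: str
    site: str
    histology: str | None  # None marks a site-level (secondary) outcome
    n_exposed_cases: int


@dataclass
class ScreeningResult:
    atc: str
    site: str
    histology: str | None
    n_exposed_cases: int
    or_high: float = math.nan
    ci_high: tuple[float, float] = (math.nan, math.nan)
    or_low: float = math.nan
    ci_low: tuple[float, float] = (math.nan, math.nan)
    or_doubling: float = math.nan
    ci_doubling: tuple[float, float] = (math.nan, math.nan)
    passed_min_cases: bool = False
    passed_high_threshold: bool = False
    passed_dose_threshold: bool = False
    low_use_neutral: bool = False
    converged: bool = False
    warnings: list[str] = field(default_factory=list)


def bottleneck_ci(n_exposed_cases: float,
                  control_ratio: float = 10.0) -> tuple[float, float]:
    """Best-case null 95% CI given the exposed-case count.

    Treats the exposed-case cell as the limiting factor: with a matched
    design at ``control_ratio`` controls per case, the optimum-precision
    variance of the log OR is 1/a + 1/(a*r) with a exposed cases; the
    unexposed cells are large enough to contribute negligibly. Pass
    ``control_ratio=math.inf`` for the one-cell limit.
    """
    if n_exposed_cases <= 0:
        raise ValueError("n_exposed_cases must be > 0")
    if control_ratio <= 0:
        raise ValueError("control_ratio must be > 0")
    a = float(n_exposed_cases)
    var = 1.0 / a if math.isinf(control_ratio) else 1.0 / a + 1.0 / (a * control_ratio)
    half = Z95 * math.sqrt(var)
    return math.exp(-half), math.exp(half)


def round_ci_display(ci: tuple[float, float]) -> tuple[float, float]:
    """One-decimal display rounding, half away from zero."""
    def r1(x: float) -> float:
        return math.floor(x * 10 + 0.5) / 10
    return r1(ci[0]), r1(ci[1])


def expected_chance_positives(n_tests: int, alpha: float = 0.05) -> int:
    """Expected count of chance-positive tests, rounded to the nearest ten."""
    if n_tests < 0:
        raise ValueError("n_tests must be >= 0")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return int(math.floor(n_tests * alpha / 10.0 + 0.5)) * 10


def _selectors(prescriptions: pd.DataFrame, atc_level: int) -> list[str]:
    codes = prescriptions["atc"].unique()
    if atc_level == 5:
        return sorted(codes)
    return sorted({c[:5] for c in codes})


def enumerate_pairs(matched_sets: pd.DataFrame, events: EventTables,
                    config: ScreenConfig = ScreenConfig(),
                    prepared: PreparedContext | None = None) -> list[PairSpec]:
    """Drug-cancer pairs meeting the minimum exposed-case rule.

    High-use case counts are computed on case subjects only, before any
    model is fitted. Histology-level outcomes are keyed by (site,
    histology); site-level outcomes pool histologies within a site.
    """
    config.validate()
    cases = matched_sets[matched_sets["role"] == "case"].reset_index(drop=True)
    if cases.empty:
        return []
    cases = cases.copy()
    cases["_window_end"] = shift_years(series_to_days(cases["index_date"]),
                                       -config.lag_years)
    ws = to_days(config.registry_start)
    if prepared is not None:
        selectors = prepared.atc_selectors(config.atc_level)
        ppos = cases["person_id"].map(prepared.pid_index).to_numpy(np.int64)
        wend = cases["_window_end"].to_numpy(np.int64)
    else:
        selectors = _selectors(events.prescriptions, config.atc_level)
    pairs: list[PairSpec] = []
    for sel in selectors:
        if prepared is not None:
            n = prepared.fills(ppos, wend, sel)
        else:
            n = count_fills_bulk(events.prescriptions, cases, sel, ws)
        high = n >= 8
        if not high.any():
            continue
        if "histology" in config.outcome_levels:
            grp = cases[high].groupby(["site", "histology"]).size()
            for (site, hist), cnt in grp.items():
                if cnt >= config.min_exposed_cases:
                    pairs.append(PairSpec(sel, site, hist, int(cnt)))
        if "site" in config.outcome_levels:
            grp = cases[high].groupby("site").size()
            for site, cnt in grp.items():
                if cnt >= config.min_exposed_cases:
                    pairs.append(PairSpec(sel, site, None, int(cnt)))
    return pairs


def _ci_covers(ci: tuple[float, float], value: float) -> bool:
    return bool(ci[0] <= value <= ci[1]) and all(map(math.isfinite, ci))


def evaluate_pair(pair: PairSpec, matched_sets: pd.DataFrame,
                  persons: pd.DataFrame, events: EventTables,
                  config: ScreenConfig,
                  prepared: PreparedContext | None = None) -> ScreeningResult:
    """Fit both models for one pair and set the cascade flags."""
    if pair.histology is None:
        subset = matched_sets[matched_sets["site"] == pair.site]
    else:
        subset = matched_sets[(matched_sets["site"] == pair.site)
                              & (matched_sets["histology"] == pair.histology)]
    res = ScreeningResult(atc=pair.atc, site=pair.site, histology=pair.histology,
                          n_exposed_cases=0)
    try:
        design = build_design(subset, persons, events.prescriptions,
                              events.hospital_dx, pair.atc,
                              lag_years=config.lag_years,
                              registry_start=config.registry_start,
                              prepared=prepared)
        cat = fit_categorical_model(design)
        dose = fit_dose_response_model(design)
    except FitError as exc:
        res.warnings.append(str(exc))
        return res
    res.n_exposed_cases = cat.n_exposed_cases
    res.or_high = cat.or_for("high")
    res.ci_high = cat.ci_for("high")
    res.or_low = cat.or_for("low")
    res.ci_low = cat.ci_for("low")
    res.or_doubling = dose.or_for("log2_fills")
    res.ci_doubling = dose.ci_for("log2_fills")
    res.converged = bool(cat.converged and dose.converged)
    res.warnings = cat.warnings + dose.warnings
    apply_cascade(res, config, cat_converged=cat.converged,
                  dose_converged=dose.converged)
    return res


def apply_cascade(res: ScreeningResult, config: ScreenConfig,
                  cat_converged: bool = True,
                  dose_converged: bool = True) -> ScreeningResult:
    """Set the bottleneck and cascade flags from the fitted CIs.

    Threshold comparisons are strict (> 1.25 and > 1); the exposed-case
    minimum is inclusive (>= 25). Non-converged fits never pass.
    """
    res.passed_min_cases = res.n_exposed_cases >= config.min_exposed_cases
    res.passed_high_threshold = bool(
        res.passed_min_cases and cat_converged
        and math.isfinite(res.ci_high[0])
        and res.ci_high[0] > config.high_threshold)
    res.passed_dose_threshold = bool(
        res.passed_high_threshold and dose_converged
        and math.isfinite(res.ci_doubling[0])
        and res.ci_doubling[0] > 1.0)
    res.low_use_neutral = _ci_covers(res.ci_low, 1.0)
    return res


def run_screen(persons: pd.DataFrame, events: EventTables,
               matched_sets: pd.DataFrame,
               config: ScreenConfig = ScreenConfig()) -> list[ScreeningResult]:
    """Screen every enumerated pair; per-pair failures are flagged, not fatal.

    Results are ordered by high-use OR descending with deterministic
    tie-breaks (atc, site ascending), mirroring a top-associations table.
    """
    config.validate()
    prepared = PreparedContext(persons, events.prescriptions,
                               events.hospital_dx,
                               registry_start=config.registry_start)
    pairs = enumerate_pairs(matched_sets, events, config, prepared=prepared)
    results = [evaluate_pair(p, matched_sets, persons, events, config,
                             prepared=prepared)
               for p in pairs]
    return sort_results(results)


def sort_results(results: list[ScreeningResult]) -> list[ScreeningResult]:
    def key(r: ScreeningResult):
        orv = r.or_high if math.isfinite(r.or_high) else -math.inf
        return (-orv, r.atc, r.site, r.histology or "")
    return sorted(results, key=key)


RESULT_COLUMNS = [
    "atc", "site", "histology", "outcome_level", "n_exposed_cases",
    "or_high", "ci_high_lower", "ci_high_upper",
    "or_low", "ci_low_lower", "ci_low_upper",
    "or_doubling", "ci_doubling_lower", "ci_doubling_upper",
    "passed_min_cases", "passed_high_threshold", "passed_dose_threshold",
    "low_use_neutral", "converged", "warnings",
]


def results_to_frame(results: list[ScreeningResult]) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    rows = []
    for r in results:
        rows.append({
            "atc": r.atc, "site": r.site,
            "histology": "" if r.histology is None else r.histology,
            "outcome_level": "site" if r.histology is None else "histology",
            "n_exposed_cases": r.n_exposed_cases,
            "or_high": r.or_high, "ci_high_lower": r.ci_high[0],
            "ci_high_upper": r.ci_high[1],
            "or_low": r.or_low, "ci_low_lower": r.ci_low[0],
            "ci_low_upper": r.ci_low[1],
            "or_doubling": r.or_doubling,
            "ci_doubling_lower": r.ci_doubling[0],
            "ci_doubling_upper": r.ci_doubling[1],
            "passed_min_cases": r.passed_min_cases,
            "passed_high_threshold": r.passed_high_threshold,
            "passed_dose_threshold": r.passed_dose_threshold,
            "low_use_neutral": r.low_use_neutral,
            "converged": r.converged,
            "warnings": "; ".join(r.warnings),
        })
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
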