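"""Case eligibility and risk-set sampling of matched controls.

Cases are first primary cancers (nonmelanoma skin cancer never counts)
diagnosed inside the study window by adults with at least ten years of
uninterrupted residency before diagnosis. Controls are drawn by risk-set
(density) sampling: for each case, up to ``n_controls`` persons of the same
sex and birth year who are alive, resident, migration-clean and cancer-free
at the case's index date. Future cases are eligible before their own
diagnosis, and a person may be sampled for several sets; under this scheme
the conditional odds ratio estimates the incidence rate ratio of the
underlying cohort.

Sampling uses an independent RNG stream per case, keyed by the global seed
and the case's identifier, so adding or removing one case never perturbs
the controls of another.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dates import series_to_days, shift_years, to_days, year_of
from .errors import ConfigError
from .registry import EventTables

EXCLUSION_ORDER = ("min_age", "prior_cancer", "migration")


@dataclass(frozen=True)
class EligibilityRules:
    min_age_years: int = 18
    migration_lookback_years: int = 10
    study_start: str = "2001-01-01"
    study_end: str = "2018-12-31"
    nmsc_site_code: str = "C44"  # ignored both as outcome and as prior cancer

    def validate(self) -> None:
        if self.min_age_years < 0:
            raise ConfigError("min_age_years", "must be >= 0")
        if self.migration_lookback_years <= 0:
            raise ConfigError("migration_lookback_years", "must be > 0")
        if to_days(self.study_start) >= to_days(self.study_end):
            raise ConfigError("study_start", "must precede study_end")


def _first_cancer(cancers: pd.DataFrame, nmsc_site: str) -> pd.DataFrame:
    """First non-NMSC cancer record per person: person_id, dx_date, icd10, morphology."""
    if cancers.empty:
        return pd.DataFrame(columns=["person_id", "icd10", "morphology", "dx_date"])
    c = cancers[cancers["icd10"] != nmsc_site]
    c = c.sort_values(["person_id", "dx_date"], kind="stable")
    return c.groupby("person_id", as_index=False).first()


def find_cases(persons: pd.DataFrame, events: EventTables,
               rules: EligibilityRules = EligibilityRules()) -> pd.DataFrame:
    """Eligible cases: person_id, index_date, site, histology.

    A person qualifies iff their first-ever non-NMSC cancer falls inside the
    study window, they are at least ``min_age_years`` old at diagnosis, and
    their entry into observation predates the diagnosis by at least
    ``migration_lookback_years`` calendar years.
    """
    rules.validate()
    first = _first_cancer(events.cancers, rules.nmsc_site_code)
    if first.empty:
        return pd.DataFrame(columns=["person_id", "index_date", "site", "histology"])
    d0, d1 = to_days(rules.study_start), to_days(rules.study_end)
    merged = first.merge(persons, on="person_id", how="inner")
    dx = series_to_days(merged["dx_date"])
    birth = series_to_days(merged["birth_date"])
    entry = series_to_days(merged["entry_date"])
    in_window = (dx >= d0) & (dx <= d1)
    adult = birth <= shift_years(dx, -rules.min_age_years)
    settled = entry <= shift_years(dx, -rules.migration_lookback_years)
    keep = in_window & adult & settled
    out = pd.DataFrame({
        "person_id": merged["person_id"][keep],
        "index_date": merged["dx_date"][keep],
        "site": merged["icd10"][keep],
        "histology": merged["morphology"][keep],
    })
    return out.sort_values(["index_date", "person_id"], kind="stable",
                           ignore_index=True)


def attrition_report(persons: pd.DataFrame, events: EventTables,
                     rules: EligibilityRules = EligibilityRules()) -> pd.DataFrame:
    """Exclusion counts over candidate cases, one row per rule plus 'eligible'.

    Candidates are persons with any non-NMSC cancer inside the study window
    (their earliest in-window record defines the tentative index date). Each
    excluded candidate is counted once, under the first failing rule in the
    fixed order min_age -> prior_cancer -> migration.
    """
    rules.validate()
    d0, d1 = to_days(rules.study_start), to_days(rules.study_end)
    c = events.cancers
    c = c[c["icd10"] != rules.nmsc_site_code]
    counts = dict.fromkeys(EXCLUSION_ORDER, 0)
    if c.empty:
        counts["eligible"] = 0
        return pd.DataFrame({"rule": list(counts), "n": list(counts.values())})
    day = series_to_days(c["dx_date"])
    in_win = c[(day >= d0) & (day <= d1)]
    cand = (in_win.sort_values(["person_id", "dx_date"], kind="stable")
            .groupby("person_id", as_index=False).first())
    earliest = (c.sort_values(["person_id", "dx_date"], kind="stable")
                .groupby("person_id", as_index=False).first()
                .rename(columns={"dx_date": "first_any_date"})
                [["person_id", "first_any_date"]])
    m = cand.merge(earliest, on="person_id").merge(persons, on="person_id")
    dx = series_to_days(m["dx_date"])
    birth = series_to_days(m["birth_date"])
    entry = series_to_days(m["entry_date"])
    first_any = series_to_days(m["first_any_date"])
    fail_age = birth > shift_years(dx, -rules.min_age_years)
    fail_prior = first_any < dx
    fail_migr = entry > shift_years(dx, -rules.migration_lookback_years)
    counts["min_age"] = int(fail_age.sum())
    counts["prior_cancer"] = int((~fail_age & fail_prior).sum())
    counts["migration"] = int((~fail_age & ~fail_prior & fail_migr).sum())
    counts["eligible"] = int((~fail_age & ~fail_prior & ~fail_migr).sum())
    return pd.DataFrame({"rule": list(counts), "n": list(counts.values())})


def _case_rng(rng_seed: int, case_id: str) -> np.random.Generator:
    # per-case counter-based stream: stable under addition/removal of cases
    return np.random.default_rng(
        np.random.SeedSequence([int(rng_seed), zlib.crc32(case_id.encode())]))


def sample_controls(cases: pd.DataFrame, persons: pd.DataFrame,
                    events: EventTables,
                    rules: EligibilityRules = EligibilityRules(),
                    n_controls: int = 10, rng_seed: int = 0) -> pd.DataFrame:
    """Risk-set sample up to ``n_controls`` controls per case.

    Returns the matched-set table with one row per subject: set_id, role
    ('case'/'control'), person_id, index_date, site, histology. Sets that
    exhaust their risk set keep the case row with zero control rows.
    """
    rules.validate()
    if n_controls < 0:
        raise ConfigError("n_controls", "must be >= 0")
    birth = series_to_days(persons["birth_date"])
    entry = series_to_days(persons["entry_date"])
    exit_ = series_to_days(persons["exit_date"])
    byear = year_of(birth)
    pid = persons["person_id"].to_numpy()
    sex = persons["sex"].to_numpy()

    first = _first_cancer(events.cancers, rules.nmsc_site_code)
    first_day = np.full(len(persons), np.iinfo(np.int64).max)
    if not first.empty:
        pos = pd.Series(np.arange(len(persons)), index=persons["person_id"])
        loc = pos.reindex(first["person_id"]).to_numpy()
        first_day[loc.astype(int)] = series_to_days(first["dx_date"])

    groups: dict[tuple[str, int], np.ndarray] = {
        k: g.to_numpy() for k, g in
        pd.Series(np.arange(len(persons))).groupby([pd.Series(sex), pd.Series(byear)])
    }

    cases = cases.sort_values(["index_date", "person_id"], kind="stable",
                              ignore_index=True)
    case_pos = pd.Series(np.arange(len(persons)), index=persons["person_id"])
    rows: list[tuple] = []
    idx_days = series_to_days(cases["index_date"])
    lookback = shift_years(idx_days, -rules.migration_lookback_years)
    adult_cut = shift_years(idx_days, -rules.min_age_years)
    for i, case in enumerate(cases.itertuples(index=False)):
        d = int(idx_days[i])
        ci = int(case_pos[case.person_id])
        set_id = f"S{i:06d}"
        rows.append((set_id, "case", case.person_id, case.index_date,
                     case.site, case.histology))
        g = groups.get((sex[ci], int(byear[ci])))
        if g is None:
            continue
        elig = ((entry[g] <= lookback[i]) & (d < exit_[g])
                & (first_day[g] > d) & (birth[g] <= adult_cut[i]) & (g != ci))
        pool = g[elig]
        if pool.size == 0:
            continue
        rng = _case_rng(rng_seed, str(case.person_id))
        k = min(n_controls, pool.size)
        chosen = rng.choice(pool, size=k, replace=False)
        for c in np.sort(chosen):
            rows.append((set_id, "control", pid[c], case.index_date,
                         case.site, case.histology))
    return pd.DataFrame(rows, columns=["set_id", "role", "person_id",
                                       "index_date", "site", "histology"])
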