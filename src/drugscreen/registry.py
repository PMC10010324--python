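"""Synthetic prescription/cancer registry generator and file round-trip.

Emulates the schema and statistical structure of linked national health
registries: a civil-registration table (sex, birth, residency interval,
education), a community-pharmacy prescription stream available from a fixed
``registry_start`` (modelled on 1995), a cancer registry with site and
morphology codes, and a hospital-diagnosis stream used for comorbidity
adjustment.

Ground-truth drug effects can be planted on any cancer outcome in two modes:

``categorical``
    the cancer hazard is multiplied by ``rr_high_use`` while the person's
    lagged cumulative fill count of the drug is 8 or more;
``doubling``
    the hazard is multiplied by ``rr_per_doubling ** log2(n_lagged_fills)``
    for persons with at least one lagged fill.

Both modes lag the cumulative count by ``planting_lag_years`` (default 2)
so that the generative mechanism matches the exposure definition used in
the downstream analysis. A single standard-normal latent health score per
person can feed prescribing intensity, hospital-contact intensity,
education and the cancer hazard, producing confounding by indication at a
controllable strength.
"""
from __future__ import annotations

import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._dates import (days_to_datetime, series_to_days, shift_years,
                     shift_years_scalar, to_days)
from .errors import ConfigError, SchemaError

ATC5_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")
SEX_CODES = ("M", "F")
EDUCATION_LEVELS = ("basic", "vocational", "higher", "unknown")

# Hospital-diagnosis code pool for the generator: a spread of Charlson
# entities (so the comorbidity score varies) plus non-Charlson noise codes.
_CHARLSON_POOL = ["I21", "I50", "I70", "G45", "F01", "J44", "M05", "K25",
                  "K70", "E11", "E112", "G81", "N18", "K72", "B20"]
_NOISE_POOL = ["Z000", "J069", "M545", "R104", "K590"]


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth effect of one drug on one cancer outcome."""
    rr_high_use: float = 1.0
    rr_per_doubling: float = 1.0
    mode: str = "doubling"  # "doubling" or "categorical"


@dataclass(frozen=True)
class DrugSpec:
    """Prescribing model for one ATC level-5 substance.

    ``prodromal_boost`` adds, for persons who later develop cancer, a
    Poisson-distributed burst of extra fills during the two years before
    the diagnosis — a reverse-causation (protopathic bias) scenario that
    the exposure lag window is designed to neutralize.
    """
    atc_code: str
    prescribing_hazard: float  # per person-year probability rate of becoming a user
    refill_interval_days: float = 90.0
    mean_fills: float = 8.0
    confounder_linked: bool = False
    prodromal_boost: float = 0.0

    def validate(self) -> None:
        if not ATC5_RE.match(self.atc_code):
            raise ConfigError("atc_code", f"{self.atc_code!r} is not an ATC "
                              "level-5 code (letter, 2 digits, 2 letters, 2 digits)")
        for f in ("prescribing_hazard", "refill_interval_days", "mean_fills",
                  "prodromal_boost"):
            if getattr(self, f) < 0:
                raise ConfigError(f, "must be >= 0")


@dataclass(frozen=True)
class CancerSpec:
    """Incidence model for one cancer outcome (site + morphology)."""
    site_code: str
    histology_code: str
    baseline_hazard: float  # per person-year at the reference age (60)
    age_slope: float = 0.06  # log-hazard per year of age beyond 60
    sex_effect: float = 0.0  # log-hazard for males vs females
    confounder_coef: float = 0.0  # log-hazard per unit latent health score
    planted_effects: Mapping[str, PlantedEffect] = field(default_factory=dict)

    def validate(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard", "must be > 0")
        for atc, eff in self.planted_effects.items():
            if not ATC5_RE.match(atc):
                raise ConfigError("planted_effects", f"key {atc!r} is not ATC level 5")
            if eff.rr_high_use <= 0 or eff.rr_per_doubling <= 0:
                raise ConfigError("planted_effects", "rate ratios must be > 0")
            if eff.mode not in ("doubling", "categorical"):
                raise ConfigError("planted_effects",
                                  f"unknown planting mode {eff.mode!r}")


@dataclass
class SimulationConfig:
    n_persons: int
    drug_specs: list[DrugSpec] = field(default_factory=list)
    cancer_specs: list[CancerSpec] = field(default_factory=list)
    study_start: str = "2001-01-01"
    study_end: str = "2018-12-31"
    registry_start: str = "1995-01-01"
    confounder_strength: float = 0.0
    migration_rate: float = 0.005  # per person-year
    death_rate: float = 0.012  # per person-year
    prior_cancer_rate: float = 0.02  # fraction with a pre-study cancer record
    prior_nmsc_rate: float = 0.01  # fraction with a pre-study nonmelanoma skin cancer
    age_range: tuple[float, float] = (20.0, 90.0)  # age span at mid-study
    background_dx_rate: float = 0.08  # hospital diagnoses per person-year
    nmsc_site_code: str = "C44"
    planting_lag_years: int = 2
    hazard_step_days: int = 91  # granularity of the piecewise-constant hazard
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ConfigError("n_persons", "must be > 0")
        d_reg, d0, d1 = (to_days(self.registry_start), to_days(self.study_start),
                         to_days(self.study_end))
        if not (d_reg <= d0 < d1):
            raise ConfigError("study_start",
                              "require registry_start <= study_start < study_end")
        for f in ("confounder_strength", "background_dx_rate"):
            if getattr(self, f) < 0:
                raise ConfigError(f, "must be >= 0")
        for f in ("migration_rate", "death_rate", "prior_cancer_rate",
                  "prior_nmsc_rate"):
            v = getattr(self, f)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f, "must lie in [0, 1]")
        if not (0 < self.age_range[0] < self.age_range[1]):
            raise ConfigError("age_range", "must be an increasing positive pair")
        if self.planting_lag_years < 0:
            raise ConfigError("planting_lag_years", "must be >= 0")
        if self.hazard_step_days <= 0:
            raise ConfigError("hazard_step_days", "must be > 0")
        for spec in self.drug_specs:
            spec.validate()
        atcs = [s.atc_code for s in self.drug_specs]
        if len(set(atcs)) != len(atcs):
            raise ConfigError("drug_specs", "duplicate ATC codes")
        for spec in self.cancer_specs:
            spec.validate()
            for atc in spec.planted_effects:
                if atc not in atcs:
                    raise ConfigError("planted_effects",
                                      f"{atc} not present in drug_specs")


@dataclass
class EventTables:
    """Prescription, cancer and hospital-diagnosis event streams."""
    prescriptions: pd.DataFrame  # person_id, atc, fill_date
    cancers: pd.DataFrame        # person_id, icd10, morphology, dx_date
    hospital_dx: pd.DataFrame    # person_id, icd10, dx_date


@dataclass
class GroundTruth:
    """Simulation-internal quantities, emitted to side files only."""
    planted: pd.DataFrame       # atc, site, histology, planted_rr_high, planted_rr_doubling, mode
    latent_health: pd.DataFrame  # person_id, latent_health


def _person_ids(n: int) -> np.ndarray:
    return np.array([f"P{i:07d}" for i in range(n)])


def simulate_registry(config: SimulationConfig):
    """Generate (persons, events, truth) under ``config``.

    Deterministic given ``config.rng_seed``: the returned tables are sorted
    canonically and two runs with the same config are identical.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_persons
    d_reg = to_days(config.registry_start)
    d0 = to_days(config.study_start)
    d1 = to_days(config.study_end)
    admin_end = d1 + 366  # administrative censoring shortly after study end
    mid = (d0 + d1) // 2

    # --- persons -----------------------------------------------------------
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    age_mid = rng.uniform(config.age_range[0], config.age_range[1], n)
    birth = (mid - age_mid * 365.2425).astype(np.int64)
    latent = rng.standard_normal(n)

    p_immigrant = min(1.0, config.migration_rate * 20.0)
    immigrant = rng.random(n) < p_immigrant
    entry = birth.copy()
    if immigrant.any():
        entry[immigrant] = rng.integers(d0 - 25 * 365, d1 - 365,
                                        int(immigrant.sum()))
        entry = np.maximum(entry, birth)

    rate = config.death_rate + config.migration_rate
    if rate > 0:
        t_years = rng.exponential(1.0 / rate, n)
    else:
        t_years = np.full(n, np.inf)
    exit_ = np.minimum(entry + t_years * 365.25, float(admin_end)).astype(np.int64)
    exit_ = np.maximum(exit_, entry + 1)

    edu_score = config.confounder_strength * latent + rng.standard_normal(n)
    cuts = np.quantile(edu_score, [1 / 3, 2 / 3])
    education = np.where(edu_score < cuts[0], "basic",
                         np.where(edu_score < cuts[1], "vocational", "higher"))
    education = np.where(rng.random(n) < 0.05, "unknown", education)

    pid = _person_ids(n)

    # --- pre-study cancer records (exercise the exclusion rules) -----------
    cancer_rows: list[tuple[int, str, str, int]] = []  # (person_idx, site, hist, day)
    if config.cancer_specs and config.prior_cancer_rate > 0:
        prior = rng.random(n) < config.prior_cancer_rate
        lo = np.maximum(entry, birth + 18 * 365)
        hi = np.minimum(d0 - 1, exit_ - 1)
        ok = prior & (lo < hi)
        idx = np.flatnonzero(ok)
        if idx.size:
            dates = lo[idx] + (rng.random(idx.size) * (hi[idx] - lo[idx])).astype(np.int64)
            which = rng.integers(0, len(config.cancer_specs), idx.size)
            for i, d, w in zip(idx, dates, which):
                cs = config.cancer_specs[int(w)]
                cancer_rows.append((int(i), cs.site_code, cs.histology_code, int(d)))
    if config.prior_nmsc_rate > 0:
        nmsc = rng.random(n) < config.prior_nmsc_rate
        lo = np.maximum(entry, birth + 18 * 365)
        hi = np.minimum(d0 - 1, exit_ - 1)
        ok = nmsc & (lo < hi)
        idx = np.flatnonzero(ok)
        if idx.size:
            dates = lo[idx] + (rng.random(idx.size) * (hi[idx] - lo[idx])).astype(np.int64)
            for i, d in zip(idx, dates):
                cancer_rows.append((int(i), config.nmsc_site_code, "8090", int(d)))

    # --- prescriptions: renewal streams per drug ---------------------------
    # fills[atc] = (person_idx array, fill day array), kept for planting.
    fills: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    wstart = np.maximum(entry, d_reg)
    obs_years = np.clip((exit_ - wstart) / 365.25, 0.0, None)
    for spec in config.drug_specs:
        haz = np.full(n, spec.prescribing_hazard)
        if spec.confounder_linked:
            haz = haz * np.exp(config.confounder_strength * latent)
        p_user = 1.0 - np.exp(-haz * obs_years)
        users = np.flatnonzero(rng.random(n) < p_user)
        if users.size == 0:
            fills[spec.atc_code] = (np.empty(0, np.int64), np.empty(0, np.int64))
            continue
        first = wstart[users] + (rng.random(users.size)
                                 * (exit_[users] - wstart[users])).astype(np.int64)
        nf_mean = max(spec.mean_fills - 1.0, 1e-9)
        lam = rng.gamma(1.3, nf_mean / 1.3, users.size)
        nf = 1 + rng.poisson(lam)
        total = int(nf.sum())
        person_rep = np.repeat(users, nf)
        gaps = np.clip(rng.exponential(spec.refill_interval_days, total), 1.0, None)
        starts = np.concatenate(([0], np.cumsum(nf)[:-1]))
        gaps[starts] = 0.0
        cs = np.cumsum(gaps)
        rel = cs - np.repeat(cs[starts], nf)
        dates = np.repeat(first, nf) + rel.astype(np.int64)
        keep = dates < np.repeat(exit_[users], nf)
        fills[spec.atc_code] = (person_rep[keep], dates[keep])

    # --- cancer incidence: piecewise-constant hazards over short periods ---
    at_risk = np.ones(n, dtype=bool)
    male = sex == "M"
    step = int(config.hazard_step_days)
    for ys in range(d0, d1 + 1, step):
        ye = min(ys + step, d1 + 1)
        if ys >= ye:
            continue
        frac = (ye - ys) / 365.25
        ym = (ys + ye) // 2
        lag_cut = shift_years_scalar(ym, -config.planting_lag_years)
        resident = (entry <= ym) & (ym < exit_)
        risk = at_risk & resident
        age = (ym - birth) / 365.25
        hit_specs: list[np.ndarray] = []
        for cs_spec in config.cancer_specs:
            loghaz = (math.log(cs_spec.baseline_hazard)
                      + cs_spec.age_slope * (age - 60.0)
                      + cs_spec.sex_effect * male
                      + cs_spec.confounder_coef * latent)
            mult = np.ones(n)
            for atc, eff in cs_spec.planted_effects.items():
                p_idx, p_day = fills[atc]
                lagged = np.bincount(p_idx[p_day < lag_cut], minlength=n)
                if eff.mode == "categorical":
                    mult = mult * np.where(lagged >= 8, eff.rr_high_use, 1.0)
                else:
                    ever = lagged >= 1
                    logmult = np.where(ever,
                                       np.log2(np.maximum(lagged, 1))
                                       * math.log(eff.rr_per_doubling), 0.0)
                    mult = mult * np.exp(logmult)
            p_event = 1.0 - np.exp(-np.exp(loghaz) * mult * frac)
            hit_specs.append(risk & (rng.random(n) < p_event))
        if not hit_specs:
            continue
        hit_any = np.logical_or.reduce(hit_specs)
        idx = np.flatnonzero(hit_any)
        if idx.size == 0:
            continue
        hit_mat = np.stack([h[idx] for h in hit_specs])  # (n_specs, n_hit)
        # if several outcomes fire in the same year, pick one uniformly
        u = rng.random(idx.size)
        counts = hit_mat.sum(axis=0)
        pick = np.minimum((u * counts).astype(int), counts - 1)
        spec_choice = np.array([np.flatnonzero(hit_mat[:, j])[pick[j]]
                                for j in range(idx.size)])
        lo = np.maximum(ys, entry[idx])
        hi = np.maximum(np.minimum(ye, exit_[idx]), lo + 1)
        ddate = lo + (rng.random(idx.size) * (hi - lo)).astype(np.int64)
        for i, s, d in zip(idx, spec_choice, ddate):
            cs_spec = config.cancer_specs[int(s)]
            cancer_rows.append((int(i), cs_spec.site_code, cs_spec.histology_code,
                                int(d)))
        at_risk[idx] = False

    # --- prodromal (protopathic) extra fills -------------------------------
    first_cancer_day = np.full(n, np.iinfo(np.int64).max)
    for i, site, _h, d in cancer_rows:
        if site != config.nmsc_site_code and d >= d0:
            first_cancer_day[i] = min(first_cancer_day[i], d)
    for spec in config.drug_specs:
        if spec.prodromal_boost <= 0:
            continue
        sick = np.flatnonzero(first_cancer_day < np.iinfo(np.int64).max)
        if sick.size == 0:
            continue
        extra = rng.poisson(spec.prodromal_boost, sick.size)
        tot = int(extra.sum())
        if tot == 0:
            continue
        p_rep = np.repeat(sick, extra)
        dx_rep = np.repeat(first_cancer_day[sick], extra)
        lo = np.maximum.reduce([shift_years(dx_rep, -2),
                                entry[p_rep], np.full(tot, d_reg)])
        hi = np.maximum(np.minimum(dx_rep, exit_[p_rep]), lo + 1)
        dts = lo + (rng.random(tot) * (hi - lo)).astype(np.int64)
        old_p, old_d = fills[spec.atc_code]
        fills[spec.atc_code] = (np.concatenate([old_p, p_rep]),
                                np.concatenate([old_d, dts]))

    # --- hospital diagnoses ------------------------------------------------
    hosp_years = np.clip((exit_ - np.maximum(entry, d_reg)) / 365.25, 0.0, None)
    lam = config.background_dx_rate * hosp_years * np.exp(
        np.clip(0.7 * config.confounder_strength * latent, -3.0, 3.0))
    k = rng.poisson(np.clip(lam, 0.0, 60.0))
    tot = int(k.sum())
    hp = np.repeat(np.arange(n), k)
    pool = np.array(_CHARLSON_POOL + _NOISE_POOL)
    w = np.concatenate([np.full(len(_CHARLSON_POOL), 0.5 / len(_CHARLSON_POOL)),
                        np.full(len(_NOISE_POOL), 0.5 / len(_NOISE_POOL))])
    codes = pool[rng.choice(len(pool), tot, p=w)]
    lo = np.maximum(entry, d_reg)[hp]
    hi = np.maximum(exit_[hp], lo + 1)
    hdates = lo + (rng.random(tot) * (hi - lo)).astype(np.int64)

    # --- assemble ----------------------------------------------------------
    persons = pd.DataFrame({
        "person_id": pid,
        "sex": sex,
        "birth_date": days_to_datetime(birth),
        "entry_date": days_to_datetime(entry),
        "exit_date": days_to_datetime(exit_),
        "education": education,
    })

    if fills:
        rx_p = np.concatenate([fills[a][0] for a in sorted(fills)])
        rx_d = np.concatenate([fills[a][1] for a in sorted(fills)])
        rx_a = np.concatenate([np.full(fills[a][0].size, a, dtype=object)
                               for a in sorted(fills)])
    else:
        rx_p = np.empty(0, np.int64)
        rx_d = np.empty(0, np.int64)
        rx_a = np.empty(0, object)
    prescriptions = pd.DataFrame({
        "person_id": pid[rx_p] if rx_p.size else np.empty(0, object),
        "atc": rx_a,
        "fill_date": days_to_datetime(rx_d),
    }).sort_values(["person_id", "atc", "fill_date"], kind="stable",
                   ignore_index=True)

    if cancer_rows:
        ci = np.array([r[0] for r in cancer_rows])
        cancers = pd.DataFrame({
            "person_id": pid[ci],
            "icd10": [r[1] for r in cancer_rows],
            "morphology": [r[2] for r in cancer_rows],
            "dx_date": days_to_datetime(np.array([r[3] for r in cancer_rows])),
        }).sort_values(["person_id", "dx_date"], kind="stable", ignore_index=True)
    else:
        cancers = pd.DataFrame({"person_id": pd.Series(dtype=object),
                                "icd10": pd.Series(dtype=object),
                                "morphology": pd.Series(dtype=object),
                                "dx_date": pd.Series(dtype="datetime64[ns]")})

    hospital = pd.DataFrame({
        "person_id": pid[hp] if tot else np.empty(0, object),
        "icd10": codes if tot else np.empty(0, object),
        "dx_date": days_to_datetime(hdates),
    }).sort_values(["person_id", "dx_date"], kind="stable", ignore_index=True)

    planted = []
    for cs_spec in config.cancer_specs:
        for atc, eff in sorted(cs_spec.planted_effects.items()):
            planted.append((atc, cs_spec.site_code, cs_spec.histology_code,
                            eff.rr_high_use, eff.rr_per_doubling, eff.mode))
    truth = GroundTruth(
        planted=pd.DataFrame(planted, columns=["atc", "site", "histology",
                                               "planted_rr_high",
                                               "planted_rr_doubling", "mode"]),
        latent_health=pd.DataFrame({"person_id": pid, "latent_health": latent}),
    )
    events = EventTables(prescriptions=prescriptions, cancers=cancers,
                         hospital_dx=hospital)
    return persons, events, truth


# --------------------------------------------------------------------------
# file round-trip
# --------------------------------------------------------------------------

_DATE_COLS = {
    "persons.csv": ["birth_date", "entry_date", "exit_date"],
    "prescriptions.csv": ["fill_date"],
    "cancers.csv": ["dx_date"],
    "hospital_dx.csv": ["dx_date"],
}
_COLUMNS = {
    "persons.csv": ["person_id", "sex", "birth_date", "entry_date", "exit_date",
                    "education"],
    "prescriptions.csv": ["person_id", "atc", "fill_date"],
    "cancers.csv": ["person_id", "icd10", "morphology", "dx_date"],
    "hospital_dx.csv": ["person_id", "icd10", "dx_date"],
}


def write_registry(persons: pd.DataFrame, events: EventTables, directory,
                   truth: GroundTruth | None = None,
                   config: SimulationConfig | None = None) -> None:
    """Write the registry as ISO-date CSV files under ``directory``.

    ``truth`` (planted effects and the latent health side file) and a small
    ``meta.json`` (registry/study dates, seed) are written when available.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tables = {"persons.csv": persons,
              "prescriptions.csv": events.prescriptions,
              "cancers.csv": events.cancers,
              "hospital_dx.csv": events.hospital_dx}
    for name, df in tables.items():
        out = df.copy()
        for c in _DATE_COLS[name]:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        out.to_csv(directory / name, index=False)
    if truth is not None:
        truth.planted.to_csv(directory / "truth.csv", index=False)
        truth.latent_health.to_csv(directory / "latent_health.csv", index=False)
    if config is not None:
        meta = {"registry_start": str(config.registry_start),
                "study_start": str(config.study_start),
                "study_end": str(config.study_end),
                "rng_seed": int(config.rng_seed),
                "n_persons": int(config.n_persons)}
        (directory / "meta.json").write_text(json.dumps(meta, indent=1))


def _read_csv(path: Path):
    name = path.name
    if not path.exists():
        raise SchemaError(name, "file missing")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[name] if c not in df.columns]
    if missing:
        raise SchemaError(name, f"missing columns {missing}")
    for c in _DATE_COLS[name]:
        parsed = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & (df[c] != "")
        if bad.any():
            raise SchemaError(name, "unparseable ISO-8601 date",
                              line=int(bad.idxmax()) + 1, column=c)
        df[c] = parsed
    return df


def read_registry(directory, validate: bool = True):
    """Read (persons, events) from ``directory``; validates invariants.

    Raises :class:`SchemaError` naming the file, row and column on the
    first violation found.
    """
    directory = Path(directory)
    persons = _read_csv(directory / "persons.csv")
    rx = _read_csv(directory / "prescriptions.csv")
    cancers = _read_csv(directory / "cancers.csv")
    hosp = _read_csv(directory / "hospital_dx.csv")
    events = EventTables(prescriptions=rx, cancers=cancers, hospital_dx=hosp)
    if validate:
        registry_start = None
        meta_path = directory / "meta.json"
        if meta_path.exists():
            registry_start = json.loads(meta_path.read_text()).get("registry_start")
        validate_registry(persons, events, registry_start=registry_start)
    return persons, events


def validate_registry(persons: pd.DataFrame, events: EventTables,
                      registry_start=None) -> None:
    """Full-scan schema and containment checks; raises SchemaError."""
    bad_sex = ~persons["sex"].isin(SEX_CODES)
    if bad_sex.any():
        raise SchemaError("persons.csv", f"unknown sex code "
                          f"{persons['sex'][bad_sex].iloc[0]!r}",
                          line=int(bad_sex.idxmax()) + 1, column="sex")
    bad_edu = ~persons["education"].isin(EDUCATION_LEVELS)
    if bad_edu.any():
        raise SchemaError("persons.csv", f"unknown education level "
                          f"{persons['education'][bad_edu].iloc[0]!r}",
                          line=int(bad_edu.idxmax()) + 1, column="education")
    entry = series_to_days(persons["entry_date"])
    exit_ = series_to_days(persons["exit_date"])
    bad = entry >= exit_
    if bad.any():
        raise SchemaError("persons.csv", "entry_date must precede exit_date",
                          line=int(np.argmax(bad)) + 1, column="entry_date")
    interval = pd.DataFrame({"person_id": persons["person_id"],
                             "_entry": entry, "_exit": exit_})
    for name, df, col in (("prescriptions.csv", events.prescriptions, "fill_date"),
                          ("cancers.csv", events.cancers, "dx_date"),
                          ("hospital_dx.csv", events.hospital_dx, "dx_date")):
        if df.empty:
            continue
        merged = df.reset_index().merge(interval, on="person_id", how="left")
        if merged["_entry"].isna().any():
            r = merged[merged["_entry"].isna()].iloc[0]
            raise SchemaError(name, f"unknown person_id {r['person_id']!r}",
                              line=int(r["index"]) + 1, column="person_id")
        day = series_to_days(merged[col])
        outside = (day < merged["_entry"].to_numpy()) | (day >= merged["_exit"].to_numpy())
        if outside.any():
            r = merged[outside].iloc[0]
            raise SchemaError(name, "event date outside the person's "
                              "[entry_date, exit_date) interval",
                              line=int(r["index"]) + 1, column=col)
        if name == "prescriptions.csv" and registry_start is not None:
            early = day < to_days(registry_start)
            if early.any():
                r = merged[early].iloc[0]
                raise SchemaError(name, f"prescription precedes registry_start "
                                  f"({registry_start})",
                                  line=int(r["index"]) + 1, column=col)
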