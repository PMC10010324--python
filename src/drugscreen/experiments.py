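"""Simulation experiments validating the screening design end to end.

These functions define the fixed study conditions for the two headline
simulation checks and are shared by the test suite, the acceptance script
and the analysis drivers:

- parameter recovery: registries with one drug planted at a high-use rate
  ratio of 3.0 (categorical mode) and another at 1.4 per doubling of
  cumulative fills (doubling mode); the pipeline's 95% CIs should cover
  the planted values in the large majority of replicates, which also
  demonstrates that the risk-set sampled conditional OR estimates the
  incidence rate ratio;
- null calibration: registries with no planted effects and no confounding;
  across many drug-cancer pairs the high-use 95% CI should contain 1 about
  95% of the time.

Replicate registries are deliberately scaled down (a few thousand persons
against millions in a national registry) so a replicate runs in well under
a second; the corresponding loss of precision is absorbed by the Wald CIs
themselves, which is exactly what the coverage checks exercise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .case_control import EligibilityRules, find_cases, sample_controls
from .clr import fit_categorical_model, fit_dose_response_model
from .errors import FitError
from .exposure import build_design
from .registry import (CancerSpec, DrugSpec, PlantedEffect, SimulationConfig,
                       simulate_registry)
from .screening import ScreenConfig, run_screen

RR_HIGH_PLANTED = 3.0
RR_DOUBLING_PLANTED = 1.4


def recovery_config(seed: int, n_persons: int = 4000) -> SimulationConfig:
    """One scaled-down registry with both planting modes represented."""
    return SimulationConfig(
        n_persons=n_persons,
        age_range=(45.0, 80.0),
        confounder_strength=0.0,
        migration_rate=0.003,
        death_rate=0.012,
        prior_cancer_rate=0.01,
        prior_nmsc_rate=0.005,
        drug_specs=[
            DrugSpec("A10BA02", prescribing_hazard=0.035, mean_fills=14.0),
            DrugSpec("C03AA03", prescribing_hazard=0.035, mean_fills=14.0),
        ],
        cancer_specs=[
            CancerSpec("C50", "8500", baseline_hazard=0.002, age_slope=0.04,
                       planted_effects={
                           "A10BA02": PlantedEffect(rr_high_use=RR_HIGH_PLANTED,
                                                    mode="categorical"),
                           "C03AA03": PlantedEffect(
                               rr_per_doubling=RR_DOUBLING_PLANTED,
                               mode="doubling"),
                       }),
        ],
        rng_seed=seed,
    )


def null_config(seed: int, n_persons: int = 12000, n_drugs: int = 25,
                n_cancers: int = 4) -> SimulationConfig:
    """A registry with many independent null drugs and several cancers.

    Prescribing intensity is set so that most drug-cancer pairs clear the
    25-exposed-case bottleneck at this registry size, keeping the pair
    count per replicate near n_drugs * n_cancers.
    """
    letters = "ABCDGHJLMNRS"
    drugs = [DrugSpec(f"{letters[i % len(letters)]}{i % 100:02d}AA{i % 100:02d}",
                      prescribing_hazard=0.045, mean_fills=14.0)
             for i in range(n_drugs)]
    sites = ["C18", "C61", "C50", "C67", "C34", "C25"]
    hists = ["8140", "8500", "8070", "8120", "8046", "8010"]
    cancers = [CancerSpec(sites[j % len(sites)], hists[j % len(hists)],
                          baseline_hazard=0.0018, age_slope=0.04)
               for j in range(n_cancers)]
    return SimulationConfig(
        n_persons=n_persons,
        age_range=(45.0, 80.0),
        confounder_strength=0.0,
        migration_rate=0.003,
        death_rate=0.012,
        prior_cancer_rate=0.01,
        drug_specs=drugs,
        cancer_specs=cancers,
        rng_seed=seed,
    )


@dataclass
class PairEstimate:
    atc: str
    site: str
    histology: str
    n_exposed_cases: int
    or_high: float
    ci_high: tuple[float, float]
    or_doubling: float
    ci_doubling: tuple[float, float]
    converged: bool


def fit_planted_pairs(config: SimulationConfig,
                      n_controls: int = 10) -> list[PairEstimate]:
    """Run the full pipeline on one registry and fit every planted pair."""
    persons, events, truth = simulate_registry(config)
    rules = EligibilityRules(study_start=config.study_start,
                             study_end=config.study_end,
                             nmsc_site_code=config.nmsc_site_code)
    cases = find_cases(persons, events, rules)
    sets = sample_controls(cases, persons, events, rules,
                           n_controls=n_controls, rng_seed=config.rng_seed)
    out: list[PairEstimate] = []
    for row in truth.planted.itertuples(index=False):
        subset = sets[(sets["site"] == row.site)
                      & (sets["histology"] == row.histology)]
        if subset.empty:
            continue
        design = build_design(subset, persons, events.prescriptions,
                              events.hospital_dx, row.atc,
                              registry_start=config.registry_start)
        try:
            cat = fit_categorical_model(design)
            dose = fit_dose_response_model(design)
        except FitError:
            continue
        out.append(PairEstimate(
            atc=row.atc, site=row.site, histology=row.histology,
            n_exposed_cases=cat.n_exposed_cases,
            or_high=cat.or_for("high"), ci_high=cat.ci_for("high"),
            or_doubling=dose.or_for("log2_fills"),
            ci_doubling=dose.ci_for("log2_fills"),
            converged=bool(cat.converged and dose.converged)))
    return out


def recovery_experiment(base_seed: int, n_replicates: int = 100,
                        n_persons: int = 4000) -> pd.DataFrame:
    """Coverage of the planted rate ratios across replicate registries.

    Returns one row per replicate with the high-use estimate for the
    categorically planted drug and the per-doubling estimate for the
    doubling-planted drug, plus CI-coverage indicators for the truths.
    """
    seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)
    rows = []
    for rep, seed in enumerate(seeds):
        ests = fit_planted_pairs(recovery_config(int(seed), n_persons))
        rec: dict = {"replicate": rep, "seed": int(seed)}
        for e in ests:
            if e.atc == "A10BA02":
                rec.update(or_high=e.or_high, ci_high_lo=e.ci_high[0],
                           ci_high_hi=e.ci_high[1],
                           covers_high=(e.ci_high[0] <= RR_HIGH_PLANTED
                                        <= e.ci_high[1]),
                           n_exposed_cases_high=e.n_exposed_cases,
                           converged_high=e.converged)
            elif e.atc == "C03AA03":
                rec.update(or_doubling=e.or_doubling,
                           ci_doub_lo=e.ci_doubling[0],
                           ci_doub_hi=e.ci_doubling[1],
                           covers_doubling=(e.ci_doubling[0]
                                            <= RR_DOUBLING_PLANTED
                                            <= e.ci_doubling[1]),
                           converged_doubling=e.converged)
        rows.append(rec)
    return pd.DataFrame(rows)


def null_calibration_experiment(base_seed: int, n_replicates: int = 3,
                                n_persons: int = 12000, n_drugs: int = 20,
                                n_cancers: int = 4,
                                min_exposed_cases: int = 25) -> pd.DataFrame:
    """Per-pair null behaviour of the screen across replicate registries.

    Returns one row per converged drug-cancer pair with the high-use OR,
    its CI, and indicators {CI covers 1} and {lower limit > 1}.
    """
    seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)
    frames = []
    for rep, seed in enumerate(seeds):
        config = null_config(int(seed), n_persons, n_drugs, n_cancers)
        persons, events, _truth = simulate_registry(config)
        rules = EligibilityRules(study_start=config.study_start,
                                 study_end=config.study_end,
                                 nmsc_site_code=config.nmsc_site_code)
        cases = find_cases(persons, events, rules)
        sets = sample_controls(cases, persons, events, rules,
                               rng_seed=config.rng_seed)
        screen_cfg = ScreenConfig(min_exposed_cases=min_exposed_cases,
                                  registry_start=config.registry_start,
                                  outcome_levels=("histology",))
        results = run_screen(persons, events, sets, screen_cfg)
        rows = [{
            "replicate": rep, "atc": r.atc, "site": r.site,
            "n_exposed_cases": r.n_exposed_cases,
            "or_high": r.or_high,
            "ci_lo": r.ci_high[0], "ci_hi": r.ci_high[1],
            "covers_1": r.ci_high[0] <= 1.0 <= r.ci_high[1],
            "exceeds_1": r.ci_high[0] > 1.0,
            "or_doubling": r.or_doubling,
            "doubling_covers_1": r.ci_doubling[0] <= 1.0 <= r.ci_doubling[1],
        } for r in results if r.converged]
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)
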