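"""End-to-end pipeline: simulate -> sample -> screen -> summarize.

A flat YAML configuration carries every tunable constant; the defaults are
the design constants of the screening protocol (2-year lag, 10 controls
per case, 25 exposed cases minimum, high-use lower-CI threshold 1.25,
ATC level 5, study window 2001-2018). A run manifest records the seed, a
hash of the resolved configuration, per-stage row counts and a SHA-256
digest of every output file, so a rerun with the same manifest inputs
reproduces the outputs byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .case_control import EligibilityRules, attrition_report, find_cases, \
    sample_controls
from .errors import ConfigError
from .registry import (CancerSpec, DrugSpec, PlantedEffect, SimulationConfig,
                       simulate_registry, write_registry)
from .screening import (ScreenConfig, expected_chance_positives,
                        results_to_frame, run_screen, sort_results)


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    n_persons: int = 20000
    lag_years: int = 2
    control_ratio: int = 10
    min_exposed_cases: int = 25
    high_threshold: float = 1.25
    atc_level: int = 5
    study_start: str = "2001-01-01"
    study_end: str = "2018-12-31"
    registry_start: str = "1995-01-01"
    confounder_strength: float = 0.0
    outcome_levels: tuple[str, ...] = ("histology",)
    drugs: list[dict] = field(default_factory=list)
    cancers: list[dict] = field(default_factory=list)

    def validate(self) -> None:
        for f in ("control_ratio", "high_threshold"):
            if getattr(self, f) <= 0:
                raise ConfigError(f, "must be > 0")
        for f in ("lag_years", "min_exposed_cases"):
            if getattr(self, f) < 0:
                raise ConfigError(f, "must be >= 0")
        self.simulation_config().validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(sorted(unknown)[0], "unknown configuration key")
        if "outcome_levels" in raw:
            raw["outcome_levels"] = tuple(raw["outcome_levels"])
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        drugs = [DrugSpec(**d) for d in self.drugs]
        cancers = []
        for c in self.cancers:
            c = dict(c)
            planted = {atc: PlantedEffect(**eff)
                       for atc, eff in c.pop("planted_effects", {}).items()}
            cancers.append(CancerSpec(planted_effects=planted, **c))
        return SimulationConfig(
            n_persons=self.n_persons, drug_specs=drugs, cancer_specs=cancers,
            study_start=self.study_start, study_end=self.study_end,
            registry_start=self.registry_start,
            confounder_strength=self.confounder_strength,
            planting_lag_years=self.lag_years, rng_seed=self.seed)

    def canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # a path, not a scientific parameter
        d["outcome_levels"] = list(d["outcome_levels"])
        return json.dumps(d, sort_keys=True)


def default_config(out_dir: str = "results/pipeline",
                   seed: int = 0) -> PipelineConfig:
    """Demonstration panel: a dozen drugs (two with planted effects, one
    confounder-linked, one protopathic) against five cancer outcomes."""
    drugs = [
        {"atc_code": "A10BA02", "prescribing_hazard": 0.030, "mean_fills": 14.0},
        {"atc_code": "C03AA03", "prescribing_hazard": 0.030, "mean_fills": 14.0},
        {"atc_code": "C07AB02", "prescribing_hazard": 0.030, "mean_fills": 12.0},
        {"atc_code": "C07AB03", "prescribing_hazard": 0.015, "mean_fills": 12.0},
        {"atc_code": "N05BA02", "prescribing_hazard": 0.012, "mean_fills": 8.0,
         "confounder_linked": True},
        {"atc_code": "J01CA08", "prescribing_hazard": 0.020, "mean_fills": 6.0,
         "prodromal_boost": 3.0},
        {"atc_code": "M01AE01", "prescribing_hazard": 0.025, "mean_fills": 9.0},
        {"atc_code": "R03AC02", "prescribing_hazard": 0.015, "mean_fills": 10.0},
        {"atc_code": "N02BE01", "prescribing_hazard": 0.030, "mean_fills": 7.0},
        {"atc_code": "C09AA02", "prescribing_hazard": 0.020, "mean_fills": 12.0},
        {"atc_code": "G03CX01", "prescribing_hazard": 0.010, "mean_fills": 10.0},
        {"atc_code": "B01AC06", "prescribing_hazard": 0.025, "mean_fills": 12.0},
    ]
    cancers = [
        {"site_code": "C50", "histology_code": "8500", "baseline_hazard": 0.0016,
         "age_slope": 0.04,
         "planted_effects": {"A10BA02": {"rr_high_use": 3.0,
                                         "mode": "categorical"},
                             "C03AA03": {"rr_per_doubling": 1.4,
                                         "mode": "doubling"}}},
        {"site_code": "C18", "histology_code": "8140", "baseline_hazard": 0.0016,
         "age_slope": 0.05},
        {"site_code": "C61", "histology_code": "8140", "baseline_hazard": 0.0014,
         "age_slope": 0.06, "sex_effect": 20.0},
        {"site_code": "C34", "histology_code": "8046", "baseline_hazard": 0.0012,
         "age_slope": 0.05},
        {"site_code": "C67", "histology_code": "8120", "baseline_hazard": 0.0008,
         "age_slope": 0.05, "sex_effect": 0.8},
    ]
    # sex_effect 20 on C61 makes prostate-like outcomes effectively male-only
    return PipelineConfig(out_dir=out_dir, seed=seed, drugs=drugs,
                          cancers=cancers)


def summarize(results, k: int = 10) -> dict:
    """Cascade stage counts plus top-k tables by high-use and doubling OR."""
    frame = results_to_frame(sort_results(list(results)))
    n_pairs = len(frame)
    stage1 = int(frame["passed_high_threshold"].sum()) if n_pairs else 0
    stage2 = int(frame["passed_dose_threshold"].sum()) if n_pairs else 0
    cols = ["atc", "site", "histology", "n_exposed_cases", "or_high",
            "ci_high_lower", "ci_high_upper", "or_doubling",
            "ci_doubling_lower", "ci_doubling_upper", "or_low",
            "ci_low_lower", "ci_low_upper", "low_use_neutral"]
    top_high = frame.head(k)[cols] if n_pairs else pd.DataFrame(columns=cols)
    by_doub = (frame.sort_values(["or_doubling", "atc", "site"],
                                 ascending=[False, True, True],
                                 kind="stable").head(k)[cols]
               if n_pairs else pd.DataFrame(columns=cols))
    return {"n_pairs": n_pairs, "n_stage1": stage1, "n_stage2": stage2,
            "expected_chance_positives": expected_chance_positives(n_pairs)
            if n_pairs else 0,
            "top_by_or_high": top_high.reset_index(drop=True),
            "top_by_or_doubling": by_doub.reset_index(drop=True)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_summary_md(path: Path, summary: dict) -> None:
    lines = ["# Screening summary", "",
             f"- pairs examined (>= min exposed cases): {summary['n_pairs']}",
             f"- stage 1 (high-use lower CI > 1.25): {summary['n_stage1']}",
             f"- stage 2 (+ doubling lower CI > 1): {summary['n_stage2']}",
             f"- expected chance positives at alpha=0.05: "
             f"{summary['expected_chance_positives']}", "",
             "## Top pairs by high-use OR", "",
             summary["top_by_or_high"].to_string(index=False), "",
             "## Top pairs by dose-doubling OR", "",
             summary["top_by_or_doubling"].to_string(index=False), ""]
    path.write_text("\n".join(lines))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> sample -> screen; write artifacts and manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation_config()
    persons, events, truth = simulate_registry(sim)
    registry_dir = out / "registry"
    write_registry(persons, events, registry_dir, truth=truth, config=sim)

    rules = EligibilityRules(study_start=config.study_start,
                             study_end=config.study_end)
    cases = find_cases(persons, events, rules)
    attrition = attrition_report(persons, events, rules)
    sets = sample_controls(cases, persons, events, rules,
                           n_controls=config.control_ratio,
                           rng_seed=config.seed)
    sets_path = out / "matched_sets.csv"
    sets_out = sets.copy()
    sets_out["index_date"] = pd.to_datetime(sets_out["index_date"]).dt.strftime("%Y-%m-%d")
    sets_out.to_csv(sets_path, index=False)
    attrition.to_csv(out / "attrition.csv", index=False)

    screen_cfg = ScreenConfig(lag_years=config.lag_years,
                              registry_start=config.registry_start,
                              min_exposed_cases=config.min_exposed_cases,
                              high_threshold=config.high_threshold,
                              atc_level=config.atc_level,
                              outcome_levels=config.outcome_levels)
    results = run_screen(persons, events, sets, screen_cfg)
    frame = results_to_frame(results)
    frame.to_csv(out / "screening_results.csv", index=False)
    summary = summarize(results)
    _write_summary_md(out / "summary.md", summary)

    files = ["matched_sets.csv", "attrition.csv", "screening_results.csv",
             "summary.md"] + [f"registry/{p.name}"
                              for p in sorted(registry_dir.iterdir())]
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()).hexdigest(),
        "row_counts": {"persons": len(persons),
                       "prescriptions": len(events.prescriptions),
                       "cancers": len(events.cancers),
                       "hospital_dx": len(events.hospital_dx),
                       "cases": len(cases),
                       "matched_set_rows": len(sets),
                       "pairs_screened": summary["n_pairs"],
                       "stage1": summary["n_stage1"],
                       "stage2": summary["n_stage2"]},
        "outputs": {f: _sha256(out / f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return {"persons": persons, "events": events, "truth": truth,
            "cases": cases, "matched_sets": sets, "results": results,
            "summary": summary, "manifest": manifest}
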