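"""Shared fixtures: hand-built micro-registries and one simulated registry."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from drugscreen.registry import (CancerSpec, DrugSpec, EventTables,
                                 PlantedEffect, SimulationConfig,
                                 simulate_registry)

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


def persons_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a persons table from sparse dicts with sensible defaults."""
    defaults = {"sex": "F", "birth_date": "1950-06-15",
                "entry_date": None, "exit_date": "2020-01-01",
                "education": "basic"}
    out = []
    for i, row in enumerate(rows):
        r = {"person_id": f"P{i:03d}", **defaults, **row}
        if r["entry_date"] is None:
            r["entry_date"] = r["birth_date"]
        out.append(r)
    df = pd.DataFrame(out)
    for c in ("birth_date", "entry_date", "exit_date"):
        df[c] = pd.to_datetime(df[c])
    return df


def events_frame(prescriptions=(), cancers=(), hospital=()) -> EventTables:
    """Build event tables from (person_id, ...) tuples."""
    rx = pd.DataFrame(list(prescriptions),
                      columns=["person_id", "atc", "fill_date"])
    rx["fill_date"] = pd.to_datetime(rx["fill_date"]) if len(rx) else \
        pd.Series(dtype="datetime64[ns]")
    ca = pd.DataFrame(list(cancers),
                      columns=["person_id", "icd10", "morphology", "dx_date"])
    ca["dx_date"] = pd.to_datetime(ca["dx_date"]) if len(ca) else \
        pd.Series(dtype="datetime64[ns]")
    ho = pd.DataFrame(list(hospital), columns=["person_id", "icd10", "dx_date"])
    ho["dx_date"] = pd.to_datetime(ho["dx_date"]) if len(ho) else \
        pd.Series(dtype="datetime64[ns]")
    return EventTables(prescriptions=rx, cancers=ca, hospital_dx=ho)


def small_config(seed: int = 123, n_persons: int = 3000) -> SimulationConfig:
    return SimulationConfig(
        n_persons=n_persons,
        age_range=(40.0, 80.0),
        drug_specs=[
            DrugSpec("C07AB02", prescribing_hazard=0.03, mean_fills=12.0),
            DrugSpec("A10BA02", prescribing_hazard=0.02, mean_fills=10.0),
        ],
        cancer_specs=[
            CancerSpec("C50", "8500", baseline_hazard=0.002, age_slope=0.04),
            CancerSpec("C18", "8140", baseline_hazard=0.0015, age_slope=0.05),
        ],
        prior_cancer_rate=0.03,
        prior_nmsc_rate=0.02,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def small_registry():
    """One moderately sized null registry shared across test modules."""
    config = small_config()
    persons, events, truth = simulate_registry(config)
    return config, persons, events, truth
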