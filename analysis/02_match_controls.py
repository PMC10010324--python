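#!/usr/bin/env python
"""Select cases and risk-set sample matched controls.

Reads results/registry/, applies the eligibility rules (adult, first
primary cancer in 2001-2018, ten migration-free years), reports the
attrition per exclusion rule, and samples up to 10 controls per case
matched on sex and birth year. Writes matched_sets.csv and attrition.csv.
"""
import argparse
from pathlib import Path

import pandas as pd

from drugscreen.case_control import (EligibilityRules, attrition_report,
                                     find_cases, sample_controls)
from drugscreen.registry import read_registry

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--registry", type=Path,
                    default=ROOT / "results" / "registry")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    persons, events = read_registry(args.registry)
    rules = EligibilityRules()
    attrition = attrition_report(persons, events, rules)
    cases = find_cases(persons, events, rules)
    sets = sample_controls(cases, persons, events, rules, rng_seed=args.seed)
    n_controls = int((sets["role"] == "control").sum())
    per_set = sets[sets["role"] == "control"].groupby("set_id").size()

    out = sets.copy()
    out["index_date"] = pd.to_datetime(out["index_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(args.out_dir / "matched_sets.csv", index=False)
    attrition.to_csv(args.out_dir / "attrition.csv", index=False)

    print("attrition over candidate cases (first failing rule):")
    print(attrition.to_string(index=False))
    print(f"\ncases matched: {len(cases)}; controls sampled: {n_controls} "
          f"(mean {n_controls / max(len(cases), 1):.2f} per case, "
          f"min {per_set.min() if len(per_set) else 0}, max "
          f"{per_set.max() if len(per_set) else 0})")
    print(f"matched sets -> {args.out_dir / 'matched_sets.csv'}")


if __name__ == "__main__":
    main()
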