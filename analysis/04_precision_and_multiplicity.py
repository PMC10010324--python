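#!/usr/bin/env python
"""Analytic side calculations behind the screen's design constants.

Tabulates the best-achievable null 95% CI as a function of the exposed-case
count (the bottleneck analysis motivating the >= 25 rule) and the expected
number of chance-positive associations for screens of various sizes.
Writes two small tables under results/tables/.
"""
import argparse
from pathlib import Path

import pandas as pd

from drugscreen.screening import (bottleneck_ci, expected_chance_positives,
                                  round_ci_display)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results" / "tables")
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for a in (5, 10, 25, 50, 100, 250, 1000):
        lo, hi = bottleneck_ci(a, 10)
        dlo, dhi = round_ci_display((lo, hi))
        rows.append({"exposed_cases": a, "ci_lower": round(lo, 4),
                     "ci_upper": round(hi, 4), "display": f"{dlo}-{dhi}"})
    bottleneck = pd.DataFrame(rows)
    bottleneck.to_csv(args.out_dir / "bottleneck_precision.csv", index=False)
    print("best-case null 95% CI by exposed-case count (10 controls/case):")
    print(bottleneck.to_string(index=False))

    rows = [{"n_pairs": n, "alpha": 0.05,
             "expected_chance_positives": expected_chance_positives(n, 0.05)}
            for n in (13577, 8996, 1000, 100)]
    multiplicity = pd.DataFrame(rows)
    multiplicity.to_csv(args.out_dir / "chance_positives.csv", index=False)
    print("\nexpected chance positives at the 5% level:")
    print(multiplicity.to_string(index=False))


if __name__ == "__main__":
    main()
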