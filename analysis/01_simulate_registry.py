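#!/usr/bin/env python
"""Generate the demonstration registry.

Simulates a scaled-down national-registry panel (a dozen drugs against
five cancer outcomes, with one drug-cancer pair planted in each dosing
mode, one confounder-linked anxiolytic and one protopathic antibiotic)
and writes the CSV tables under results/registry/.
"""
import argparse
from pathlib import Path

from drugscreen.pipeline import default_config
from drugscreen.registry import simulate_registry, write_registry

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-persons", type=int, default=20000)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "registry")
    args = ap.parse_args()

    cfg = default_config(seed=args.seed)
    cfg.n_persons = args.n_persons
    sim = cfg.simulation_config()
    persons, events, truth = simulate_registry(sim)
    write_registry(persons, events, args.out, truth=truth, config=sim)
    print(f"registry written to {args.out}")
    print(f"  persons:        {len(persons):>8}")
    print(f"  prescriptions:  {len(events.prescriptions):>8}")
    print(f"  cancer records: {len(events.cancers):>8}")
    print(f"  hospital dx:    {len(events.hospital_dx):>8}")
    print(f"  planted effects:\n{truth.planted.to_string(index=False)}")


if __name__ == "__main__":
    main()
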