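#!/usr/bin/env python
"""MMSET-PHF19 correlation split by t(4;14) status.

The generator couples the two designated genes only in translocation-negative
patients, while t(4;14) shifts MMSET expression up independently of PHF19.
This script measures the Pearson correlation within each subgroup of every
training cohort and writes the table under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from mmrisk import SimulationConfig, correlation_by_subgroup, simulate_challenge

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    config = SimulationConfig(seed=args.seed)
    train, _ = simulate_challenge(config, 4, 4)

    rows = []
    for cohort in train:
        res = correlation_by_subgroup(cohort, "MMSET", "PHF19")
        rows.append({
            "cohort_id": cohort.cohort_id,
            "r_t414_negative": None if res.r_negative is None
            else round(res.r_negative, 3),
            "n_negative": res.n_negative,
            "r_t414_positive": None if res.r_positive is None
            else round(res.r_positive, 3),
            "n_positive": res.n_positive,
        })
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "subgroup_correlation.csv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    print(f"\nTable written to {out}")

    print("\nThe MMSET-PHF19 correlation appears only in t(4;14)-negative "
          f"patients (target r = {config.within_negative_corr}); in "
          "translocation carriers the enhancer-driven MMSET shift swamps the "
          "shared factor and the correlation vanishes.")


if __name__ == "__main__":
    main()
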