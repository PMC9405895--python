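#!/usr/bin/env python
"""Group comparisons across breathing modes.

Friedman omnibus tests with Durbin-Conover post-hoc pairwise comparisons and
per-index FDR adjustment, over the cohort indices from 03.  Writes
results/group_stats.csv (one row per index and pairwise comparison) and
results/group_descriptives.csv (median [range] per index and mode).
"""

from pathlib import Path

import pandas as pd

from rtpcflow.pipeline import RunConfig, run_group

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = pd.read_csv(ROOT / "results" / "cohort_indices.csv")
    stats, desc = run_group(results, RunConfig())
    stats.to_csv(ROOT / "results" / "group_stats.csv", index=False)
    desc.to_csv(ROOT / "results" / "group_descriptives.csv", index=False)

    print("pairwise comparisons (FDR-adjusted p):\n")
    show = stats[["index", "comparison", "friedman_p", "p_raw", "p_fdr"]].copy()
    for c in ("friedman_p", "p_raw", "p_fdr"):
        show[c] = show[c].map(lambda v: f"{v:.4g}")
    print(show.to_string(index=False))

    sig = stats[stats["p_fdr"] < 0.05]
    print(f"\n{len(sig)} of {len(stats)} comparisons significant at FDR < 0.05")
    print(f"wrote {ROOT / 'results' / 'group_stats.csv'}")
    print(f"wrote {ROOT / 'results' / 'group_descriptives.csv'}")


if __name__ == "__main__":
    main()
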