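#!/usr/bin/env python
"""Summary surfaces: hybrid ranking, trait correlations, damage counts.

Ranks hybrids by grain yield against the commercial checks (top-15 and
group means), computes pairwise Pearson correlations between traits on the
across-environment BLUPs with their significance thresholds, and counts
hybrids under the foliar-damage resistance cutoff (score < 4).
"""

import argparse
from pathlib import Path

import pandas as pd

from diallelkit.config import RunConfig
from diallelkit.summaries import (correlate_traits, count_below,
                                  rank_and_summarize)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    cfg = RunConfig()

    blups = pd.read_csv(args.results / "entry_means_blup.csv")
    wide = blups.pivot_table(index="entry", columns="trait", values="value")
    checks = [c for c in cfg.checks if c in wide.index]
    experimental = wide.drop(index=checks)

    ranking = rank_and_summarize(wide, "GY", top_n=cfg.top_n, check_ids=checks)
    ranking.ranked.rename_axis("entry").to_csv(args.results / "ranking.csv")
    ranking.group_means.rename_axis("group").to_csv(args.results / "group_means.csv")
    print("group means (GY and damage traits):")
    cols = [c for c in ("GY", "FD1", "FD2", "FD3", "ED", "ER") if c in wide.columns]
    print(ranking.group_means[cols].round(2).to_string())

    corr = correlate_traits(experimental)
    corr.r.rename_axis("trait").to_csv(args.results / "correlations.csv")
    corr.p.rename_axis("trait").to_csv(args.results / "correlation_pvalues.csv")
    print(f"\ncritical |r| at alpha=0.05: {corr.critical_r(0.05):.3f}, "
          f"at 0.01: {corr.critical_r(0.01):.3f} (n = {len(experimental)})")
    if {"GY", "ED"} <= set(wide.columns):
        print(f"corr(GY, ED) = {corr.r.loc['GY', 'ED']:.2f}")

    for fd in ("FD1", "FD2", "FD3"):
        if fd in wide.columns:
            print(f"{fd} < 4: {count_below(experimental, fd, 4.0)} hybrids")


if __name__ == "__main__":
    main()
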