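#!/usr/bin/env python
"""Simulate the synthetic 21-parent diallel study.

Generates the full trial: 210 F1 hybrids plus four commercial checks in
two environments with two replicates in incomplete blocks, fourteen trait
columns on their published scales, and a 2,000-SNP parental panel whose
causal subset drives the grain-yield GCA.  Writes plot data, marker files
(HapMap-style and VCF) and the ground-truth sidecar under results/.
"""

import argparse
import json
from pathlib import Path

from diallelkit.config import RunConfig
from diallelkit.design import make_design
from diallelkit.io import write_hapmap, write_plot_csv, write_vcf
from diallelkit.markers import parental_genetic_values, simulate_markers
from diallelkit.pipeline import _stage_seeds
from diallelkit.simulate import simulate_study, truth_to_dict


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    cfg = RunConfig(seed=args.seed)
    seeds = _stage_seeds(cfg.seed)

    design = make_design(cfg.p, cfg.n_env, cfg.n_rep, cfg.block_size,
                         checks=list(cfg.checks))
    markers, causal = simulate_markers(
        list(design.parents), cfg.n_snps, cfg.maf_range, cfg.missing_rate,
        cfg.n_causal, seed=seeds["markers"])
    marker_gca = {t: parental_genetic_values(markers, causal)
                  for t in cfg.marker_traits}
    genetics, plots = simulate_study(design, seed=seeds["study"],
                                     marker_gca=marker_gca)

    args.out.mkdir(parents=True, exist_ok=True)
    write_plot_csv(plots, args.out / "plots.csv")
    write_hapmap(markers, args.out / "markers.hmp.txt")
    write_vcf(markers, args.out / "markers.vcf")
    (args.out / "truth.json").write_text(
        json.dumps(truth_to_dict(genetics), indent=1))

    print(f"design: {design.n_parents} parents -> {design.n_crosses} crosses "
          f"+ {len(design.checks)} checks")
    print(f"plots: {len(plots)} ({cfg.n_env} envs x {cfg.n_rep} reps)")
    print(f"markers: {markers.n_snps} SNPs, {int(causal.ne(0).sum())} causal")
    print(f"written to {args.out}/")


if __name__ == "__main__":
    main()
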