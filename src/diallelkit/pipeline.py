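"""End-to-end pipeline: simulate -> entry means -> diallel -> predict -> summarise.

Each stage writes tidy CSV tables under the output directory plus a
machine-readable ``manifest.json`` and a log recording seeds, clamped
variance components and dropped markers.  A rerun with the same
configuration produces byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .design import make_design
from .griffing import (diallel_anova, effect_tests, genetic_ratios,
                       griffing_effects, impute_missing_cells, stars,
                       variance_components)
from .io import write_hapmap, write_plot_csv, write_vcf
from .markers import filter_markers, grm, parental_genetic_values, simulate_markers
from .prediction import gblup_cv, loo_gca_predict
from .simulate import default_trait_specs, simulate_study, truth_to_dict
from .summaries import correlate_traits, count_below, rank_and_summarize
from .trial_means import entry_means, pooled_error, screen_outliers

logger = logging.getLogger(__name__)


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {name: int(rng.integers(2**31 - 1))
            for name in ("markers", "study", "cv")}


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic-study pipeline; returns a result bundle.

    Stages: (1) simulate markers and the multi-trait diallel trial, (2)
    per-environment BLUEs and across-environment BLUPs, (3) Griffing
    method-4 ANOVA, variance components, ratios and effect tests per trait,
    (4) GCA leave-one-out and GBLUP fivefold prediction, (5) rankings,
    correlations and threshold counts.  Any stage failure aborts with the
    stage name.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("diallelkit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seeds = _stage_seeds(config.seed)
    logger.info("diallelkit %s; config seed %d; stage seeds %s",
                __version__, config.seed, seeds)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stage_seeds": seeds, "outputs": {}}
    bundle: dict = {}

    def emit(name: str, frame: pd.DataFrame, **to_csv_kw) -> None:
        path = out / f"{name}.csv"
        frame.to_csv(path, float_format="%.10g", **to_csv_kw)
        manifest["outputs"][name] = str(path)

    stage = "simulate"
    try:
        design = make_design(config.p, config.n_env, config.n_rep,
                             config.block_size, checks=list(config.checks))
        markers, causal = simulate_markers(
            list(design.parents), config.n_snps, config.maf_range,
            config.missing_rate, config.n_causal, seed=seeds["markers"],
        )
        marker_gca = {
            t: parental_genetic_values(markers, causal) for t in config.marker_traits
        }
        genetics, plots = simulate_study(
            design, seed=seeds["study"], marker_gca=marker_gca,
        )
        write_plot_csv(plots, out / "plots.csv")
        write_hapmap(markers, out / "markers.hmp.txt")
        write_vcf(markers, out / "markers.vcf")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth_to_dict(genetics), fh, indent=1)
        manifest["outputs"].update({
            "plots": str(out / "plots.csv"),
            "markers_hapmap": str(out / "markers.hmp.txt"),
            "markers_vcf": str(out / "markers.vcf"),
            "truth": str(out / "truth.json"),
        })
        bundle.update(design=design, markers=markers, genetics=genetics, plots=plots)

        stage = "means"
        traits = list(config.traits)
        flagged = screen_outliers(plots, config.outlier_threshold, traits=traits)
        if len(flagged):
            logger.info("outlier screening flagged %d plot values", len(flagged))
            for _, row in flagged.iterrows():
                plots.loc[row["row"], row["trait"]] = np.nan
        blues = entry_means(plots, scope="per-env", estimator="BLUE", traits=traits)
        blups = entry_means(plots, scope="across", estimator="BLUP", traits=traits)
        errors = pooled_error(plots, traits=traits)
        emit("entry_means_blue", blues, index=False)
        emit("entry_means_blup", blups, index=False)
        emit("pooled_error", errors, index=False)
        bundle.update(blues=blues, blups=blups, errors=errors)

        stage = "diallel"
        cross_ids = [c for c in design.entries if c not in design.checks]
        anova_rows, vc_rows, ratio_rows, gca_tabs, sca_tabs = [], [], [], [], []
        anovas = {}
        for trait in traits:
            sub = blues[blues["trait"] == trait]
            wide = sub.pivot_table(index="entry", columns="env", values="value")
            wide = wide.loc[[c for c in cross_ids if c in wide.index]]
            if wide.isna().to_numpy().any():
                logger.info("trait %s: imputed %d missing entry-mean cells",
                            trait, int(wide.isna().to_numpy().sum()))
                wide = impute_missing_cells(wide)
            err = errors.set_index("trait").loc[trait]
            anova = diallel_anova(
                wide, design, config.n_rep,
                error_ms=float(err["error_ms"]), error_df=float(err["error_df"]),
                rep_ms=float(err["rep_ms"]), rep_df=float(err["rep_df"]),
            )
            anovas[trait] = anova
            at = anova.table.copy()
            at.insert(0, "trait", trait)
            anova_rows.append(at)
            vc = variance_components(anova, trait=trait)
            if vc.clamped:
                logger.info("trait %s: clamped components %s", trait, vc.clamped)
            ratios = genetic_ratios(vc, anova)
            vc_rows.append(vc.as_series().rename(trait))
            ratio_rows.append(ratios.as_series().rename(trait))

            across_means = wide.mean(axis=1)
            effects = effect_tests(
                griffing_effects(across_means, design, trait=trait), anova
            )
            gt = effects.gca.copy()
            gt.insert(0, "trait", trait)
            gt["sig"] = stars(gt["p"])
            gca_tabs.append(gt)
            st = effects.sca.copy()
            st.insert(0, "trait", trait)
            st["sig"] = stars(st["p"])
            sca_tabs.append(st)
        emit("anova", pd.concat(anova_rows).rename_axis("source"))
        emit("variance_components", pd.DataFrame(vc_rows).rename_axis("trait"))
        emit("genetic_ratios", pd.DataFrame(ratio_rows).rename_axis("trait"))
        emit("gca_effects", pd.concat(gca_tabs).rename_axis("parent"))
        emit("sca_effects", pd.concat(sca_tabs).rename_axis("cross"))
        bundle.update(anovas=anovas,
                      variance_components=pd.DataFrame(vc_rows),
                      ratios=pd.DataFrame(ratio_rows))

        stage = "predict"
        kept = filter_markers(markers, config.maf_min, config.max_missing)
        logger.info("marker QC: %d of %d SNPs retained", kept.n_snps, markers.n_snps)
        hybrid_geno = kept.hybrid_matrix(list(design.crosses))
        kinship = grm(hybrid_geno)
        pred_rows, pred_tables = [], []
        for trait in traits:
            sub = blues[blues["trait"] == trait]
            wide = sub.pivot_table(index="entry", columns="env", values="value")
            wide = wide.loc[[c for c in cross_ids if c in wide.index]]
            if wide.isna().to_numpy().any():
                wide = impute_missing_cells(wide)
            means = wide.mean(axis=1)
            loo = loo_gca_predict(means, design, trait=trait)
            gb = gblup_cv(means, kinship, config.cv_folds, seed=seeds["cv"],
                          trait=trait)
            for rep in (loo, gb):
                pred_rows.append({"trait": trait, "method": rep.method,
                                  "r": rep.r, "p": rep.p_value, "n": rep.n,
                                  "seed": rep.seed})
                tb = rep.table.copy()
                tb.insert(0, "trait", trait)
                tb.insert(1, "method", rep.method)
                pred_tables.append(tb)
        summary = pd.DataFrame(pred_rows)
        emit("prediction_summary", summary, index=False)
        emit("predictions", pd.concat(pred_tables).rename_axis("cross"))
        bundle["prediction_summary"] = summary

        stage = "summarize"
        blup_wide = blups.pivot_table(index="entry", columns="trait", values="value")
        exp_wide = blup_wide.loc[[c for c in cross_ids if c in blup_wide.index]]
        corr = correlate_traits(exp_wide)
        emit("correlations", corr.r.rename_axis("trait"))
        emit("correlation_pvalues", corr.p.rename_axis("trait"))
        ranking = rank_and_summarize(
            blup_wide, "GY", top_n=config.top_n,
            check_ids=[c for c in config.checks if c in blup_wide.index],
        )
        emit("ranking", ranking.ranked.rename_axis("entry"))
        emit("group_means", ranking.group_means.rename_axis("group"))
        fd_counts = pd.DataFrame([
            {"trait": t, "cutoff": 4.0,
             "n_below": count_below(exp_wide, t, 4.0)}
            for t in ("FD1", "FD2", "FD3") if t in exp_wide.columns
        ])
        emit("fd_counts", fd_counts, index=False)
        bundle.update(correlations=corr, ranking=ranking, fd_counts=fd_counts)
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        root.removeHandler(handler)
        handler.close()
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    bundle["manifest"] = manifest
    root.removeHandler(handler)
    handler.close()
    return bundle
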