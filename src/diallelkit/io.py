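"""File formats: plot CSVs, HapMap-style marker tables, minimal VCF.

CSV is the canonical interchange for phenotypes; markers are accepted as a
HapMap-style tab table (rs, alleles, chrom, pos, then one genotype column
per parent) or a minimal GT-only VCF.  Either marker dialect parses to the
same unified 0/2/missing inbred coding; heterozygous calls in inbreds are
set missing with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import MarkerMatrix
from .simulate import ORDINAL_TRAITS

logger = logging.getLogger(__name__)

REQUIRED_PLOT_COLUMNS = ["env", "rep", "block", "entry", "parent1", "parent2"]


def write_plot_csv(plots: pd.DataFrame, path: str | Path) -> None:
    plots.to_csv(path, index=False)


def read_plot_csv(path: str | Path) -> pd.DataFrame:
    """Read plot records, validating structure and ordinal trait ranges.

    Empty cells become missing values; ordinal damage scores outside the
    1-9 scale raise with the offending row and column named.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plot CSV {path} is missing required columns: {missing}")
    for col in ("parent1", "parent2"):
        df[col] = df[col].fillna("")
    if "is_check" not in df.columns:
        df["is_check"] = df["parent1"] == ""
    df["is_check"] = df["is_check"].astype(bool)

    trait_cols = [c for c in df.columns
                  if c not in REQUIRED_PLOT_COLUMNS + ["is_check"]]
    for col in trait_cols:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric value in column {col!r}, row {bad[0] + 2} of {path}"
                )
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if col in ORDINAL_TRAITS:
            vals = df[col].dropna()
            out = vals[(vals < 1) | (vals > 9)]
            if len(out):
                raise ValueError(
                    f"ordinal trait {col!r} has value {out.iloc[0]} outside the "
                    f"1-9 scale at row {out.index[0] + 2} of {path}"
                )
    return df


# ---------------------------------------------------------------------------
# markers: HapMap-style table


def write_hapmap(markers: MarkerMatrix, path: str | Path) -> None:
    """Write a HapMap-style tab table: rs, alleles, chrom, pos, one column
    per parent with two-letter genotypes (AA / CC / NN for missing)."""
    geno = markers.genotypes
    meta = markers.meta
    with open(path, "w") as fh:
        fh.write("rs\talleles\tchrom\tpos\t" + "\t".join(geno.index) + "\n")
        for snp in geno.columns:
            ref, alt = meta.loc[snp, "alleles"].split("/")
            calls = []
            for v in geno[snp]:
                if np.isnan(v):
                    calls.append("NN")
                elif v == 0:
                    calls.append(ref + ref)
                elif v == 2:
                    calls.append(alt + alt)
                else:  # imputed fractional dosage has no letter form
                    raise ValueError(
                        f"cannot write fractional dosage {v} at {snp}; "
                        "write the unimputed panel"
                    )
            fh.write(f"{snp}\t{meta.loc[snp, 'alleles']}\t"
                     f"{meta.loc[snp, 'chrom']}\t{meta.loc[snp, 'pos']}\t"
                     + "\t".join(calls) + "\n")


def read_hapmap(path: str | Path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    parents = [c for c in df.columns if c not in ("rs", "alleles", "chrom", "pos")]
    n_het = 0
    codes = np.full((len(parents), len(df)), np.nan)
    for m, row in df.iterrows():
        ref, alt = row["alleles"].split("/")
        for i, par in enumerate(parents):
            call = str(row[par])
            if call in ("NN", "nan", ""):
                continue
            if call == ref + ref:
                codes[i, m] = 0.0
            elif call == alt + alt:
                codes[i, m] = 2.0
            else:
                n_het += 1
    if n_het:
        logger.warning("read_hapmap: %d heterozygous/unknown inbred calls set missing", n_het)
    geno = pd.DataFrame(codes, index=parents, columns=df["rs"].tolist())
    meta = df.set_index("rs")[["chrom", "pos", "alleles"]]
    return MarkerMatrix(genotypes=geno, meta=meta)


# ---------------------------------------------------------------------------
# markers: minimal VCF (GT only)


def write_vcf(markers: MarkerMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF (0/0, 1/1, ./.) of the parental panel."""
    geno = markers.genotypes
    meta = markers.meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.index) + "\n")
        for snp in geno.columns:
            ref, alt = meta.loc[snp, "alleles"].split("/")
            calls = []
            for v in geno[snp]:
                if np.isnan(v):
                    calls.append("./.")
                elif v == 0:
                    calls.append("0/0")
                elif v == 2:
                    calls.append("1/1")
                else:
                    raise ValueError(f"cannot write fractional dosage {v} at {snp}")
            fh.write(f"{meta.loc[snp, 'chrom']}\t{meta.loc[snp, 'pos']}\t{snp}\t"
                     f"{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n")


def read_vcf(path: str | Path) -> MarkerMatrix:
    """Read a GT-only VCF into the unified inbred 0/2/missing coding.

    Heterozygous calls (impossible in a fully inbred line) are set missing
    and counted in a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    parents = list(vcf.samples)
    ids, chroms, pos, alleles, rows = [], [], [], [], []
    n_het = 0
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        pos.append(var.POS)
        alleles.append(f"{var.REF}/{var.ALT[0] if var.ALT else '.'}")
        gt = var.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        het = gt == 1
        n_het += int(het.sum())
        gt[het | (gt == 3)] = np.nan
        rows.append(gt)
    if n_het:
        logger.warning("read_vcf: %d heterozygous inbred calls set missing", n_het)
    codes = np.array(rows).T if rows else np.empty((len(parents), 0))
    geno = pd.DataFrame(codes, index=parents, columns=ids)
    meta = pd.DataFrame({"chrom": chroms, "pos": pos, "alleles": alleles}, index=ids)
    return MarkerMatrix(genotypes=geno, meta=meta)


def read_markers(path: str | Path, format: str | None = None) -> MarkerMatrix:
    """Read a marker file, inferring the dialect from the extension.

    ``format``: "hapmap" or "vcf"; inferred from the filename when None.
    """
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "hapmap"
    if format == "vcf":
        return read_vcf(path)
    if format == "hapmap":
        return read_hapmap(path)
    raise ValueError(f"unknown marker format {format!r}")


def check_parent_consistency(plots: pd.DataFrame, markers: MarkerMatrix) -> None:
    """Raise if phenotype and marker files disagree on the parent set."""
    pheno_parents = set(plots.loc[~plots["is_check"], "parent1"]) | set(
        plots.loc[~plots["is_check"], "parent2"]
    )
    pheno_parents.discard("")
    marker_parents = set(markers.parents)
    if pheno_parents != marker_parents:
        only_p = sorted(pheno_parents - marker_parents)
        only_m = sorted(marker_parents - pheno_parents)
        raise ValueError(
            "parent sets differ between phenotypes and markers; "
            f"phenotypes only: {only_p}; markers only: {only_m}"
        )
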