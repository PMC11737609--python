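"""Parental SNP panels: simulation, quality control, kinship.

Inbred parents are genotyped with biallelic SNPs coded as alt-allele counts
0/2 (homozygotes only; missing allowed).  A hybrid's genotype at a SNP is
the mean of its parents' codes, so an F1 between opposite homozygotes is 1.

Quality control mirrors common breeding practice: retain SNPs with minor
allele frequency strictly above a floor and a missing fraction strictly
below a cap, then impute the surviving missing calls to the SNP mean.

The genomic relationship matrix is the VanRaden centred cross-product
K = W W' / sum_m 2 p_m (1 - p_m), with W the column-centred genotype matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import cross_id

logger = logging.getLogger(__name__)


@dataclass
class MarkerMatrix:
    """Parent-by-SNP genotype matrix with SNP metadata.

    ``genotypes``: DataFrame indexed by parent, one column per SNP, values
    in {0, 2, NaN} for raw inbred panels (fractional values appear after
    mean imputation).  ``meta``: DataFrame indexed by SNP id with columns
    ``chrom``, ``pos`` (1-based), ``alleles`` ("A/B" strings).
    """

    genotypes: pd.DataFrame
    meta: pd.DataFrame

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def parents(self) -> list[str]:
        return list(self.genotypes.index)

    def allele_freq(self) -> pd.Series:
        """Alt-allele frequency per SNP, ignoring missing calls."""
        return self.genotypes.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> pd.Series:
        return self.genotypes.isna().mean(axis=0)

    def hybrid_matrix(self, crosses: list[tuple[str, str]]) -> pd.DataFrame:
        """Cross-by-SNP genotypes coded as the parental mean (x_i + x_j)/2."""
        geno = self.genotypes
        rows = {cross_id(a, b): (geno.loc[a].to_numpy() + geno.loc[b].to_numpy()) / 2.0
                for a, b in crosses}
        return pd.DataFrame.from_dict(rows, orient="index", columns=geno.columns)

    def validate_inbred(self) -> None:
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 2)
        if not ok.all():
            raise ValueError("inbred panel contains codes other than 0/2/missing")


def simulate_markers(
    p: int | list[str],
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    n_causal: int = 0,
    seed: int = 0,
    effect_sd: float = 1.0,
    n_chrom: int = 10,
) -> tuple[MarkerMatrix, pd.Series]:
    """Simulate an inbred parental SNP panel plus additive causal effects.

    Each SNP's alt-allele frequency is drawn uniformly within ``maf_range``;
    parental genotypes are independent Bernoulli(freq) homozygotes (0/2).
    The generator guarantees its own constraints on the *realised* panel,
    not just the drawn frequencies: each SNP is resampled until its
    realised minor-allele frequency (over observed calls) falls within
    ``maf_range``, and per-SNP missing calls are capped at
    ceil(n_parents x missing_rate), so a QC filter at thresholds looser
    than these bounds retains every SNP.

    ``n_causal`` SNPs (chosen at random) receive i.i.d. normal additive
    effects; the implied parental genetic value is the sum of effect times
    genotype, so downstream marker-based prediction has recoverable signal.

    Returns the panel and a Series of per-SNP effects (zero off the causal
    set).  SNPs are spread evenly over ``n_chrom`` chromosomes.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    if n_causal > n_snps:
        raise ValueError("n_causal cannot exceed n_snps")

    parents = [f"P{i + 1:02d}" for i in range(p)] if isinstance(p, int) else list(p)
    n_par = len(parents)
    rng = np.random.default_rng(seed)

    miss_cap = int(np.ceil(n_par * missing_rate)) if missing_rate > 0 else 0
    geno = np.empty((n_par, n_snps))
    for m in range(n_snps):
        freq = rng.uniform(lo, hi)
        for _attempt in range(1000):
            col = (rng.random(n_par) < freq).astype(float) * 2.0
            if missing_rate > 0:
                mask = rng.random(n_par) < missing_rate
                if mask.sum() > miss_cap:
                    continue
                col[mask] = np.nan
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                continue
            p_hat = obs.mean() / 2.0
            if lo <= min(p_hat, 1.0 - p_hat) <= hi:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not realise a SNP within maf_range={maf_range}")
        geno[:, m] = col

    snp_ids = [f"S{m + 1:05d}" for m in range(n_snps)]
    chroms = [str(m % n_chrom + 1) for m in range(n_snps)]
    pos = [m // n_chrom * 1000 + 1 for m in range(n_snps)]
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "alleles": ["A/C"] * n_snps}, index=snp_ids
    )
    matrix = MarkerMatrix(
        genotypes=pd.DataFrame(geno, index=parents, columns=snp_ids), meta=meta
    )

    effects = np.zeros(n_snps)
    if n_causal > 0:
        causal = rng.choice(n_snps, size=n_causal, replace=False)
        effects[causal] = rng.normal(0.0, effect_sd, size=n_causal)
    return matrix, pd.Series(effects, index=snp_ids)


def parental_genetic_values(markers: MarkerMatrix, effects: pd.Series) -> pd.Series:
    """Additive genetic value of each parent: sum_m effect_m * x_pm / 2.

    The division by two puts values on the gametic scale, so a hybrid's
    additive value is the sum of its parents' values; with no causal effects
    all values are equal (zero).  Missing genotypes are mean-imputed first.
    """
    geno = markers.genotypes.fillna(markers.genotypes.mean(axis=0))
    beta = effects.reindex(geno.columns).fillna(0.0).to_numpy()
    vals = geno.to_numpy(dtype=float) @ beta / 2.0
    return pd.Series(vals, index=markers.parents)


def filter_markers(
    markers: MarkerMatrix,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
) -> MarkerMatrix:
    """QC filter: MAF strictly > ``maf_min``, missingness strictly < ``max_missing``.

    Surviving missing calls are imputed to the SNP mean; SNP order is
    preserved.  Raises if no SNP survives.
    """
    maf = markers.maf()
    miss = markers.missing_fraction()
    keep = (maf > maf_min) & (miss < max_missing)
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"no SNPs survive QC (maf > {maf_min}, missing < {max_missing})"
        )
    if n_drop:
        logger.info(
            "filter_markers: dropped %d/%d SNPs (MAF <= %g or missing >= %g)",
            n_drop, markers.n_snps, maf_min, max_missing,
        )
    geno = markers.genotypes.loc[:, keep]
    geno = geno.fillna(geno.mean(axis=0))
    return MarkerMatrix(genotypes=geno, meta=markers.meta.loc[geno.columns])


def grm(hybrid_genotypes: pd.DataFrame) -> pd.DataFrame:
    """VanRaden genomic relationship matrix from hybrid-coded genotypes.

    ``hybrid_genotypes``: rows are hybrids (or parents), columns SNPs, codes
    on the 0..2 dosage scale.  Zero-variance SNPs contribute nothing to the
    centred cross-product and are excluded from the scaling denominator
    (with a warning).  The result is symmetric to machine precision.
    """
    if hybrid_genotypes.shape[0] < 2 or hybrid_genotypes.shape[1] < 1:
        raise ValueError("need at least 2 individuals and 1 SNP")
    x = hybrid_genotypes.to_numpy(dtype=float)
    pfreq = x.mean(axis=0) / 2.0
    w = x - 2.0 * pfreq
    het = 2.0 * pfreq * (1.0 - pfreq)
    poly = het > 0
    if not poly.all():
        warnings.warn(
            f"grm: {int((~poly).sum())} zero-variance SNPs excluded from scaling",
            stacklevel=2,
        )
    denom = het[poly].sum()
    if denom <= 0:
        raise ValueError("all SNPs are monomorphic; kinship undefined")
    k = w @ w.T / denom
    k = (k + k.T) / 2.0
    return pd.DataFrame(k, index=hybrid_genotypes.index, columns=hybrid_genotypes.index)
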