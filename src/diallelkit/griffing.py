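"""Griffing model-1 / method-4 combining-ability analysis.

Method 4 analyses the F1 crosses of a half diallel (no parents, no
reciprocals).  On a balanced set of entry means x_ij (one per cross) the
closed-form estimators are

    mu    = 2 x.. / (p (p - 1))
    g_i   = [p x_i. - 2 x..] / [p (p - 2)]
    s_ij  = x_ij - mu - g_i - g_j

with x_i. the sum of means over crosses containing parent i and x.. the
overall sum.  With missing crosses the same effects are the solution of the
least-squares problem under the sum-to-zero constraints; the balanced
closed forms coincide with that solution.

The across-environment ANOVA partitions the hybrid sum of squares into GCA
and SCA and the hybrid-by-environment sum of squares into GCA x E and
SCA x E.  Sums of squares are computed on entry means and scaled by the
replicate count r so mean squares are on the plot-equivalent scale; on that
scale GCA and SCA are tested against their environment interactions, the
interactions against the pooled plot error, and the expected-mean-squares
solution for the variance components is

    s2_SCA   = (MS_SCA - MS_SCAxE) / (r e)
    s2_GCA   = [(MS_GCA - MS_GCAxE) - (MS_SCA - MS_SCAxE)] / (r e (p - 2))
    s2_GCAxE = (MS_GCAxE - MS_SCAxE) / (r (p - 2))
    s2_SCAxE = (MS_SCAxE - s2_e) / r

with negative solutions clamped to zero.  Derived quantities:
s2_A = 2 s2_GCA, s2_D = s2_SCA, s2_P = s2_A + s2_D + s2_e, the Baker
ratio 2 s2_GCA / (2 s2_GCA + s2_SCA), and entry-mean broad-sense
heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DiallelDesign, cross_id


# ---------------------------------------------------------------------------
# effects


@dataclass
class CombiningAbilityResult:
    """GCA/SCA effect estimates for one trait.

    ``gca``: DataFrame indexed by parent with columns estimate/se/t/p;
    ``sca``: DataFrame indexed by cross id with parent1/parent2 and the same
    statistic columns.  se/t/p are NaN until ``effect_tests`` annotates them.
    """

    trait: str
    mu: float
    gca: pd.DataFrame
    sca: pd.DataFrame
    balanced: bool
    inestimable_parents: list[str] = field(default_factory=list)

    def sca_matrix(self) -> pd.DataFrame:
        """Symmetric parent-by-parent SCA matrix (NaN diagonal)."""
        parents = list(self.gca.index)
        m = pd.DataFrame(np.nan, index=parents, columns=parents)
        for c, row in self.sca.iterrows():
            m.loc[row["parent1"], row["parent2"]] = row["estimate"]
            m.loc[row["parent2"], row["parent1"]] = row["estimate"]
        return m


def _gca_design_matrix(
    crosses: list[tuple[str, str]], parents: list[str]
) -> np.ndarray:
    """Reduced design matrix [1 | G] for (mu, g_1..g_{p-1}) with sum-zero g.

    Column t (t < p-1) carries I(parent_t in cross) - I(parent_p in cross),
    absorbing the constraint g_p = -sum of the others.
    """
    pos = {par: i for i, par in enumerate(parents)}
    p = len(parents)
    x = np.zeros((len(crosses), p))
    x[:, 0] = 1.0
    for r, (a, b) in enumerate(crosses):
        for par in (a, b):
            i = pos[par]
            if i < p - 1:
                x[r, 1 + i] += 1.0
            else:
                x[r, 1:p] -= 1.0
    return x


def fit_gca_least_squares(
    means: pd.Series,
    parents: list[str],
    cross_parents: dict[str, tuple[str, str]],
) -> tuple[float, pd.Series]:
    """Constrained least-squares fit of mu and GCA on a (sub)set of crosses.

    ``means`` is indexed by cross id; crosses absent from ``means`` are
    simply omitted.  Returns (mu, g) with sum(g) = 0.  Used both by the
    missing-cross path of ``griffing_effects`` and by leave-one-hybrid-out
    prediction.
    """
    crosses = [cross_parents[c] for c in means.index]
    x = _gca_design_matrix(crosses, parents)
    coef, *_ = np.linalg.lstsq(x, means.to_numpy(dtype=float), rcond=1e-12)
    mu = coef[0]
    g = np.append(coef[1:], -coef[1:].sum())
    return float(mu), pd.Series(g, index=parents)


def griffing_effects(
    entry_means: pd.Series,
    design: DiallelDesign,
    trait: str = "trait",
) -> CombiningAbilityResult:
    """Estimate mu, GCA and SCA effects from per-cross entry means.

    ``entry_means`` is indexed by cross id ("parent1/parent2").  When all
    p(p-1)/2 crosses are present the balanced closed forms are used; with
    missing crosses the constrained least-squares path is taken.  Parents
    appearing in fewer than two available crosses have inestimable effects
    and are flagged (their estimates are NaN).
    """
    parents = list(design.parents)
    p = len(parents)
    cross_parents = design.cross_index()
    known = entry_means.dropna()
    unknown = set(known.index) - set(cross_parents)
    if unknown:
        raise ValueError(f"means contain entries not in the design: {sorted(unknown)}")

    counts = {par: 0 for par in parents}
    for c in known.index:
        a, b = cross_parents[c]
        counts[a] += 1
        counts[b] += 1
    inestimable = [par for par in parents if counts[par] < 2]

    balanced = len(known) == len(design.crosses)
    if balanced:
        x_tot = known.sum()
        x_par = pd.Series(0.0, index=parents)
        for c, val in known.items():
            a, b = cross_parents[c]
            x_par[a] += val
            x_par[b] += val
        mu = 2.0 * x_tot / (p * (p - 1))
        g = (p * x_par - 2.0 * x_tot) / (p * (p - 2))
    else:
        usable = known[[c for c in known.index
                        if counts[cross_parents[c][0]] >= 2 and counts[cross_parents[c][1]] >= 2]]
        mu, g = fit_gca_least_squares(usable, parents, cross_parents)
        g = g.astype(float)
        for par in inestimable:
            g[par] = np.nan

    sca_rows = []
    for c in [cross_id(a, b) for a, b in design.crosses]:
        a, b = cross_parents[c]
        if c in known.index:
            s = known[c] - mu - g[a] - g[b]
        else:
            s = np.nan
        sca_rows.append({"cross": c, "parent1": a, "parent2": b, "estimate": s})

    gca = pd.DataFrame({"estimate": g})
    gca["se"] = np.nan
    gca["t"] = np.nan
    gca["p"] = np.nan
    sca = pd.DataFrame(sca_rows).set_index("cross")
    for col in ("se", "t", "p"):
        sca[col] = np.nan
    return CombiningAbilityResult(
        trait=trait, mu=float(mu), gca=gca, sca=sca,
        balanced=balanced, inestimable_parents=inestimable,
    )


def impute_missing_cells(wide: pd.DataFrame) -> pd.DataFrame:
    """Fill missing entry-by-environment cells with additive fitted values.

    A per-environment entry mean can be lost entirely (e.g. both replicates
    of a plot flagged as outliers).  The balanced ANOVA path needs a full
    table, so missing cells are replaced by the least-squares fit of the
    additive entry + environment model to the observed cells — the classic
    missing-plot technique.  Returns a copy; raises if an entry is missing
    in every environment.
    """
    x = wide.astype(float).copy()
    if not x.isna().to_numpy().any():
        return x
    if x.isna().all(axis=1).any():
        bad = list(x.index[x.isna().all(axis=1)])
        raise ValueError(f"entries missing in every environment: {bad[:5]}")
    stacked = x.stack(future_stack=True).rename("value").reset_index()
    obs = stacked.dropna(subset=["value"])
    ze, entries = indicator_frame(obs.iloc[:, 0].to_numpy())
    zv, envs = indicator_frame(obs.iloc[:, 1].to_numpy())
    mat = np.hstack([ze, zv[:, 1:]])
    coef, *_ = np.linalg.lstsq(mat, obs["value"].to_numpy(), rcond=None)
    entry_eff = dict(zip(entries, coef[: len(entries)]))
    env_eff = dict(zip(envs, np.concatenate([[0.0], coef[len(entries):]])))
    for entry, env in zip(*np.nonzero(x.isna().to_numpy())):
        x.iloc[entry, env] = entry_eff[x.index[entry]] + env_eff[x.columns[env]]
    return x


def indicator_frame(levels: np.ndarray) -> tuple[np.ndarray, list]:
    uniq, inv = np.unique(levels, return_inverse=True)
    z = np.zeros((levels.size, uniq.size))
    z[np.arange(levels.size), inv] = 1.0
    return z, list(uniq)


# ---------------------------------------------------------------------------
# ANOVA


@dataclass
class AnovaTable:
    """Across-environment (or single-environment) diallel ANOVA.

    ``table``: DataFrame indexed by source with columns df, ms, F, p,
    denominator (the error-stratum row each F uses).  Mean squares are on
    the plot-equivalent scale (entry-mean sums of squares multiplied by the
    replicate count), matching how multi-environment diallel ANOVAs are
    conventionally reported.
    """

    table: pd.DataFrame
    p: int
    n_env: int
    n_rep: int
    single_env: bool = False

    def ms(self, source: str) -> float:
        return float(self.table.loc[source, "ms"])

    def df(self, source: str) -> float:
        return float(self.table.loc[source, "df"])


def _component_ss(means: pd.Series, design: DiallelDesign) -> tuple[float, float, float]:
    """(SS_total_among_crosses, SS_GCA, SS_SCA) of a balanced mean vector."""
    res = griffing_effects(means, design)
    g = res.gca["estimate"]
    fitted_g = np.array([
        g[a] + g[b] for a, b in design.crosses
    ])
    ss_gca = float((fitted_g**2).sum())
    s = res.sca["estimate"].to_numpy(dtype=float)
    ss_sca = float((s**2).sum())
    centred = means.to_numpy(dtype=float) - means.mean()
    return float((centred**2).sum()), ss_gca, ss_sca


def diallel_anova(
    entry_means_by_env: pd.DataFrame,
    design: DiallelDesign,
    n_rep: int,
    error_ms: float,
    error_df: float,
    rep_ms: float | None = None,
    rep_df: float | None = None,
) -> AnovaTable:
    """Across-environment method-4 diallel ANOVA on entry means.

    Parameters
    ----------
    entry_means_by_env : DataFrame
        Crosses (index, cross ids) by environments (columns); one BLUE per
        cell.  All crosses must be present (balanced path).
    n_rep : int
        Replicates per environment; entry-mean sums of squares are scaled
        by this so mean squares sit on the plot-equivalent scale.
    error_ms, error_df : float
        Pooled plot-level error mean square and its df (from
        ``trial_means.pooled_error``); the error stratum for the
        environment-interaction rows.  Equivalently, the entry-mean-scale
        error is this mean square divided by ``n_rep``.
    rep_ms, rep_df : float, optional
        Replicate-within-environment mean square (plot scale), reported as
        its own row when supplied.

    Degrees of freedom follow the method-4 identities: Hybrids
    p(p-1)/2 - 1, GCA p - 1, SCA p(p-3)/2, and (e-1) times each for the
    interaction rows.
    """
    p = design.n_parents
    envs = list(entry_means_by_env.columns)
    e = len(envs)
    n_crosses = design.n_crosses
    if set(entry_means_by_env.index) != set(design.entries) - set(design.checks):
        missing = (set(design.entries) - set(design.checks)) - set(entry_means_by_env.index)
        raise ValueError(f"entry means must cover all crosses; missing {sorted(missing)[:5]} ...")
    x = entry_means_by_env.astype(float)
    r = n_rep

    if e == 1:
        means = x.iloc[:, 0]
        _, ss_g, ss_s = _component_ss(means, design)
        rows = {
            "Hybrids": (n_crosses - 1, r * float(((means - means.mean())**2).sum())),
            "GCA": (p - 1, r * ss_g),
            "SCA": (p * (p - 3) // 2, r * ss_s),
            "Error": (error_df, error_ms * error_df),
        }
        tab = _assemble(rows, {"Hybrids": "SCA", "GCA": "SCA", "SCA": "Error"})
        return AnovaTable(table=tab, p=p, n_env=1, n_rep=r, single_env=True)

    grand = float(x.to_numpy().mean())
    env_means = x.mean(axis=0)
    cross_means = x.mean(axis=1)

    ss_env = r * n_crosses * float(((env_means - grand)**2).sum())
    ss_h = r * e * float(((cross_means - grand)**2).sum())
    _, ss_g_across, ss_s_across = _component_ss(cross_means, design)
    ss_gca = r * e * ss_g_across
    ss_sca = r * e * ss_s_across

    ss_g_pooled = 0.0
    ss_s_pooled = 0.0
    ss_cross_pooled = 0.0
    for env in envs:
        tot, g_k, s_k = _component_ss(x[env], design)
        ss_cross_pooled += r * tot
        ss_g_pooled += r * g_k
        ss_s_pooled += r * s_k
    ss_hxe = ss_cross_pooled - ss_h
    ss_gxe = ss_g_pooled - ss_gca
    ss_sxe = ss_s_pooled - ss_sca

    rows = {
        "Environment": (e - 1, ss_env),
    }
    if rep_ms is not None:
        rows["Rep(Env)"] = (rep_df if rep_df is not None else e * (r - 1),
                            rep_ms * (rep_df if rep_df is not None else e * (r - 1)))
    rows.update({
        "Hybrids": (n_crosses - 1, ss_h),
        "GCA": (p - 1, ss_gca),
        "SCA": (p * (p - 3) // 2, ss_sca),
        "HxE": ((e - 1) * (n_crosses - 1), ss_hxe),
        "GCAxE": ((e - 1) * (p - 1), ss_gxe),
        "SCAxE": ((e - 1) * p * (p - 3) // 2, ss_sxe),
        "Error": (error_df, error_ms * error_df),
    })
    denoms = {
        "Environment": "HxE",
        "Rep(Env)": "Error",
        "Hybrids": "HxE",
        "GCA": "GCAxE",
        "SCA": "SCAxE",
        "HxE": "Error",
        "GCAxE": "Error",
        "SCAxE": "Error",
    }
    tab = _assemble(rows, denoms)
    return AnovaTable(table=tab, p=p, n_env=e, n_rep=r)


def _assemble(rows: dict[str, tuple[float, float]], denoms: dict[str, str]) -> pd.DataFrame:
    tab = pd.DataFrame(
        {src: {"df": df, "ms": ss / df if df > 0 else np.nan}
         for src, (df, ss) in rows.items()}
    ).T
    tab["F"] = np.nan
    tab["p"] = np.nan
    tab["denominator"] = ""
    for src, den in denoms.items():
        if src not in tab.index or den not in tab.index:
            continue
        f = tab.loc[src, "ms"] / tab.loc[den, "ms"]
        tab.loc[src, "F"] = f
        tab.loc[src, "p"] = stats.f.sf(f, tab.loc[src, "df"], tab.loc[den, "df"])
        tab.loc[src, "denominator"] = den
    return tab


# ---------------------------------------------------------------------------
# variance components and ratios


@dataclass
class VarianceComponents:
    trait: str
    sigma2_gca: float
    sigma2_sca: float
    sigma2_gca_env: float
    sigma2_sca_env: float
    sigma2_e: float
    clamped: list[str] = field(default_factory=list)

    @property
    def sigma2_a(self) -> float:
        return 2.0 * self.sigma2_gca

    @property
    def sigma2_d(self) -> float:
        return self.sigma2_sca

    @property
    def sigma2_p(self) -> float:
        return self.sigma2_a + self.sigma2_d + self.sigma2_e

    def as_series(self) -> pd.Series:
        return pd.Series({
            "sigma2_GCA": self.sigma2_gca,
            "sigma2_SCA": self.sigma2_sca,
            "sigma2_GCAxE": self.sigma2_gca_env,
            "sigma2_SCAxE": self.sigma2_sca_env,
            "sigma2_e": self.sigma2_e,
            "sigma2_A": self.sigma2_a,
            "sigma2_D": self.sigma2_d,
            "sigma2_P": self.sigma2_p,
        })


def variance_components(
    anova: AnovaTable,
    p: int | None = None,
    e: int | None = None,
    r: int | None = None,
    sigma2_e: float | None = None,
    trait: str = "trait",
) -> VarianceComponents:
    """Method-4 expected-mean-squares solution for the variance components.

    ``sigma2_e`` defaults to the ANOVA error mean square; passing a
    separately estimated plot error variance (e.g. from a REML fit) changes
    the SCAxE subtraction and the phenotypic variance accordingly.
    Negative solutions are clamped to zero and recorded in ``clamped``.
    """
    p = p or anova.p
    e = e or anova.n_env
    r = r or anova.n_rep
    if anova.single_env or "GCAxE" not in anova.table.index:
        raise ValueError(
            "variance components need the across-environment ANOVA with "
            "interaction rows; a single-environment table cannot separate "
            "GCA/SCA variance from their environment interactions"
        )
    ms_gca = anova.ms("GCA")
    ms_sca = anova.ms("SCA")
    ms_gxe = anova.ms("GCAxE")
    ms_sxe = anova.ms("SCAxE")
    err = anova.ms("Error") if sigma2_e is None else sigma2_e

    raw = {
        "sigma2_SCA": (ms_sca - ms_sxe) / (r * e),
        "sigma2_GCA": ((ms_gca - ms_gxe) - (ms_sca - ms_sxe)) / (r * e * (p - 2)),
        "sigma2_GCAxE": (ms_gxe - ms_sxe) / (r * (p - 2)),
        "sigma2_SCAxE": (ms_sxe - err) / r,
    }
    clamped = [k for k, v in raw.items() if v < 0]
    clip = {k: max(v, 0.0) for k, v in raw.items()}
    return VarianceComponents(
        trait=trait,
        sigma2_gca=clip["sigma2_GCA"],
        sigma2_sca=clip["sigma2_SCA"],
        sigma2_gca_env=clip["sigma2_GCAxE"],
        sigma2_sca_env=clip["sigma2_SCAxE"],
        sigma2_e=err,
        clamped=clamped,
    )


@dataclass
class GeneticRatios:
    trait: str
    baker_ratio: float | None
    gca_sca_ratio: float | None
    heritability: float

    def as_series(self) -> pd.Series:
        return pd.Series({
            "baker_ratio": np.nan if self.baker_ratio is None else self.baker_ratio,
            "gca_sca_ratio": np.nan if self.gca_sca_ratio is None else self.gca_sca_ratio,
            "H2": self.heritability,
        })


def baker_ratio(sigma2_gca: float, sigma2_sca: float) -> float | None:
    """2 s2_GCA / (2 s2_GCA + s2_SCA); None when both components are zero.

    Values near 1 mean hybrid performance is predictable from parental GCA
    alone (additive gene action predominates).
    """
    denom = 2.0 * sigma2_gca + sigma2_sca
    if denom == 0:
        return None
    return 2.0 * sigma2_gca / denom


def genetic_ratios(
    vc: VarianceComponents,
    anova: AnovaTable,
    e: int | None = None,
    r: int | None = None,
) -> GeneticRatios:
    """Baker ratio, GCA/SCA variance ratio and entry-mean heritability.

    Broad-sense heritability on the entry-mean basis uses the hybrid rows:
    s2_G = (MS_H - MS_HxE)/(r e), s2_GxE = (MS_HxE - MS_error)/r,
    H2 = s2_G / (s2_G + s2_GxE/e + s2_e/(r e)), clamped to [0, 1].
    """
    e = e or anova.n_env
    r = r or anova.n_rep
    bk = baker_ratio(vc.sigma2_gca, vc.sigma2_sca)
    ratio = vc.sigma2_gca / vc.sigma2_sca if vc.sigma2_sca > 0 else None

    ms_h = anova.ms("Hybrids")
    ms_hxe = anova.ms("HxE") if "HxE" in anova.table.index else np.nan
    ms_err = anova.ms("Error")
    s2_g = max((ms_h - ms_hxe) / (r * e), 0.0)
    s2_gxe = max((ms_hxe - ms_err) / r, 0.0)
    denom = s2_g + s2_gxe / e + ms_err / (r * e)
    h2 = float(np.clip(s2_g / denom, 0.0, 1.0)) if denom > 0 else 0.0
    return GeneticRatios(
        trait=vc.trait, baker_ratio=bk, gca_sca_ratio=ratio, heritability=h2,
    )


# ---------------------------------------------------------------------------
# significance of effects


def effect_tests(
    result: CombiningAbilityResult,
    anova: AnovaTable,
    r: int | None = None,
    e: int | None = None,
    p: int | None = None,
) -> CombiningAbilityResult:
    """Annotate GCA/SCA effects with standard errors and two-sided t tests.

    Balanced method-4 sampling variances on the across-environment
    entry-mean scale, with the effective error variance taken from the
    stratum each effect class is tested against (the environment
    interaction across environments, the plot error within one):

        Var(g_i)  = (p - 1) / (p (p - 2)) * s2_eff
        Var(s_ij) = (p - 3) / (p - 1)     * s2_eff

    where s2_eff = MS_stratum / (r e).  Degrees of freedom are those of the
    stratum.  Stars at 0.05/0.01 are left to the presentation layer.
    """
    p = p or anova.p
    e = e or anova.n_env
    r = r or anova.n_rep
    if anova.single_env:
        # single-env convention: GCA tested against SCA, SCA against error
        eff_g = anova.ms("SCA") / (r * e)
        df_g = anova.df("SCA")
        eff_s = anova.ms("Error") / (r * e)
        df_s = anova.df("Error")
    else:
        eff_g = anova.ms("GCAxE") / (r * e)
        df_g = anova.df("GCAxE")
        eff_s = anova.ms("SCAxE") / (r * e)
        df_s = anova.df("SCAxE")

    se_g = np.sqrt((p - 1) / (p * (p - 2)) * eff_g)
    se_s = np.sqrt((p - 3) / (p - 1) * eff_s)

    gca = result.gca.copy()
    gca["se"] = se_g
    gca["t"] = gca["estimate"] / se_g
    gca["p"] = 2.0 * stats.t.sf(np.abs(gca["t"]), df_g)
    sca = result.sca.copy()
    sca["se"] = se_s
    sca["t"] = sca["estimate"] / se_s
    sca["p"] = 2.0 * stats.t.sf(np.abs(sca["t"]), df_s)
    return CombiningAbilityResult(
        trait=result.trait, mu=result.mu, gca=gca, sca=sca,
        balanced=result.balanced, inestimable_parents=result.inestimable_parents,
    )


def stars(pvalues: pd.Series) -> pd.Series:
    """Significance stars at the 0.05 (*) and 0.01 (**) levels."""
    return pvalues.map(lambda q: "**" if q < 0.01 else ("*" if q < 0.05 else ""))
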