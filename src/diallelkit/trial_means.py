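"""Entry means (BLUEs/BLUPs) from plot-level alpha-lattice data.

Stage one of the two-stage analysis: per environment, plot values are fitted
with entries fixed and replicates and incomplete blocks (nested in
replicates) random, giving per-environment BLUEs; the same model with
entries random gives shrunken BLUPs.  Across environments the model adds
random environment, replicate-within-environment and entry-by-environment
terms.  Variance components come from EM-REML (see ``mixedmodel``); missing
plots are handled by the model, never imputed.

``screen_outliers`` flags plots whose standardised residual from a per-
environment two-way (entry + replicate) fit exceeds a threshold; the
default threshold of 3.5 internally studentised residuals is a common
screening rule for replicated trials.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .mixedmodel import RandomTerm, fit_mixed, indicator

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ["env", "rep", "block", "entry", "parent1", "parent2", "is_check"]


def trait_columns(plots: pd.DataFrame) -> list[str]:
    return [c for c in plots.columns if c not in DESIGN_COLUMNS]


def screen_outliers(
    plots: pd.DataFrame,
    threshold_sd: float = 3.5,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Flag plots with |studentised residual| > ``threshold_sd``.

    Residuals come from a per-environment two-way fixed-effects fit
    (entry + replicate, by least squares) per trait; studentisation uses
    the leverage of each plot.  Returns a DataFrame of flagged rows with
    columns ``row`` (index into ``plots``), ``env``, ``entry``, ``trait``,
    ``value``, ``std_resid``.  The input is not mutated.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be > 0")
    traits = traits or trait_columns(plots)
    flagged = []
    for env, sub in plots.groupby("env", sort=True):
        if sub["rep"].nunique() < 2:
            raise ValueError(
                f"environment {env!r} has fewer than 2 replicates; "
                "residuals are unidentifiable"
            )
        for trait in traits:
            y = sub[trait].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < 3:
                continue
            ze, _ = indicator(sub.loc[ok, "entry"].to_numpy())
            zr, _ = indicator(sub.loc[ok, "rep"].to_numpy())
            x = np.hstack([ze, zr[:, 1:]])
            q, _ = np.linalg.qr(x)
            yv = y[ok]
            fitted = q @ (q.T @ yv)
            resid = yv - fitted
            lev = np.minimum((q**2).sum(axis=1), 1 - 1e-10)
            df = ok.sum() - np.linalg.matrix_rank(x)
            if df <= 0:
                continue
            mse = resid @ resid / df
            if mse <= 0:
                continue
            std = resid / np.sqrt(mse * (1 - lev))
            rows = sub.index[ok]
            for local in np.nonzero(np.abs(std) > threshold_sd)[0]:
                flagged.append({
                    "row": rows[local], "env": env,
                    "entry": sub.loc[rows[local], "entry"], "trait": trait,
                    "value": yv[local], "std_resid": std[local],
                })
    return pd.DataFrame(flagged, columns=["row", "env", "entry", "trait", "value", "std_resid"])


def _fit_one(
    sub: pd.DataFrame,
    trait: str,
    estimator: str,
    across: bool,
    variance_components: dict[str, float] | None,
) -> pd.DataFrame | None:
    y = sub[trait].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    if ok.sum() == 0:
        return None
    sub = sub.loc[ok]
    y = y[ok]

    entry = sub["entry"].to_numpy()
    rep_env = (sub["env"].astype(str) + ":" + sub["rep"].astype(str)).to_numpy()
    block = (rep_env + ":" + sub["block"].astype(str))
    terms: list[RandomTerm] = []
    if across:
        z_env, lv = indicator(sub["env"].to_numpy())
        terms.append(RandomTerm("env", z_env, lv))
    z_rep, lv = indicator(rep_env)
    terms.append(RandomTerm("rep", z_rep, lv))
    z_blk, lv = indicator(block.to_numpy())
    terms.append(RandomTerm("block", z_blk, lv))
    if across:
        ge = (sub["entry"].astype(str) + "@" + sub["env"].astype(str)).to_numpy()
        z_ge, lv = indicator(ge)
        terms.append(RandomTerm("entry_env", z_ge, lv))

    z_entry, entry_levels = indicator(entry)
    fixed = None
    if variance_components is not None:
        fixed = {t.name: variance_components.get(t.name, 0.0) for t in terms}

    if estimator == "BLUE":
        x = z_entry
        if fixed is not None:
            fit = fit_mixed(y, x, terms, fixed_variances=fixed,
                            fixed_sigma2_e=variance_components["residual"])
        else:
            fit = fit_mixed(y, x, terms)
        values = fit.beta
        ses = np.sqrt(np.maximum(np.diag(fit.cov_beta), 0.0))
    else:  # BLUP
        x = np.ones((y.size, 1))
        terms = terms + [RandomTerm("entry", z_entry, entry_levels)]
        if fixed is not None:
            fixed["entry"] = variance_components.get("entry", 0.0)
            fit = fit_mixed(y, x, terms, fixed_variances=fixed,
                            fixed_sigma2_e=variance_components["residual"])
        else:
            fit = fit_mixed(y, x, terms)
        values = fit.beta[0] + fit.u["entry"]
        ses = np.sqrt(np.maximum(fit.pev["entry"], 0.0))

    return pd.DataFrame({
        "entry": entry_levels, "trait": trait, "estimator": estimator,
        "value": values, "se": ses,
    })


def entry_means(
    plots: pd.DataFrame,
    scope: str = "per-env",
    estimator: str = "BLUE",
    traits: list[str] | None = None,
    variance_components: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Estimate entry means per trait, per environment or across environments.

    Parameters
    ----------
    plots : DataFrame
        Plot records (simulated or read from CSV).
    scope : {"per-env", "across"}
        Per-environment fits (one model per env) or a single across-
        environment model with environment and entry-by-environment random.
    estimator : {"BLUE", "BLUP"}
        Entries fixed (BLUE) or random, shrunken toward the grand mean (BLUP).
    variance_components : dict, optional
        Known variance components (keys ``rep``, ``block``, ``residual``,
        plus ``env``/``entry_env`` across environments and ``entry`` for
        BLUPs); skips REML when given.

    Returns
    -------
    DataFrame with columns ``entry, env, trait, estimator, value, se``
    (``env`` is ``"across"`` for the across-environment scope).  Entries
    absent from all plots for a trait are absent from the output (warned).
    """
    if scope not in ("per-env", "across"):
        raise ValueError(f"scope must be 'per-env' or 'across', got {scope!r}")
    if estimator not in ("BLUE", "BLUP"):
        raise ValueError(f"estimator must be 'BLUE' or 'BLUP', got {estimator!r}")
    traits = traits or trait_columns(plots)

    out = []
    all_entries = set(plots["entry"].unique())
    if scope == "per-env":
        for env, sub in plots.groupby("env", sort=True):
            for trait in traits:
                res = _fit_one(sub, trait, estimator, False, variance_components)
                if res is None:
                    continue
                res.insert(1, "env", env)
                out.append(res)
    else:
        for trait in traits:
            res = _fit_one(plots, trait, estimator, True, variance_components)
            if res is None:
                continue
            res.insert(1, "env", "across")
            out.append(res)

    if not out:
        return pd.DataFrame(columns=["entry", "env", "trait", "estimator", "value", "se"])
    table = pd.concat(out, ignore_index=True)
    missing = all_entries - set(table["entry"].unique())
    if missing:
        logger.warning("entries absent from all plots: %s", sorted(missing))
    return table


def means_wide(table: pd.DataFrame, env: str | None = None) -> pd.DataFrame:
    """Pivot a long entry-mean table to entries x traits (one env or 'across')."""
    sub = table if env is None else table[table["env"] == env]
    return sub.pivot_table(index="entry", columns="trait", values="value")


def arithmetic_entry_means(plots: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Plain per-environment arithmetic entry means (fast path).

    Equals the BLUE when the design is balanced and block/replicate
    variances are zero; used by large simulation studies where the mixed
    model adds nothing but runtime.  Returns a long table like
    ``entry_means(scope='per-env')`` without standard errors.
    """
    traits = traits or trait_columns(plots)
    melted = plots.melt(
        id_vars=["env", "entry"], value_vars=traits,
        var_name="trait", value_name="value",
    ).dropna(subset=["value"])
    g = melted.groupby(["entry", "env", "trait"], sort=True)["value"].mean().reset_index()
    g["estimator"] = "MEAN"
    g["se"] = np.nan
    return g[["entry", "env", "trait", "estimator", "value", "se"]]


def pooled_error(
    plots: pd.DataFrame,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Pooled plot-level error mean square per trait, over environments.

    Residual mean square of the per-environment two-way entry + replicate
    fit, pooled over environments (weighted by residual df); this is the
    intra-block error term that the across-environment diallel ANOVA tests
    its interaction rows against.  Returns columns ``trait, error_ms,
    error_df, rep_ms, rep_df`` (replicate-within-environment mean square on
    the plot scale).
    """
    traits = traits or trait_columns(plots)
    rows = []
    for trait in traits:
        ss = 0.0
        df = 0
        rep_ss = 0.0
        rep_df = 0
        for _, sub in plots.groupby("env", sort=True):
            y = sub[trait].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            if ok.sum() < 3:
                continue
            yv = y[ok]
            ze, _ = indicator(sub.loc[ok, "entry"].to_numpy())
            zr, _ = indicator(sub.loc[ok, "rep"].to_numpy())
            x = np.hstack([ze, zr[:, 1:]])
            q, _ = np.linalg.qr(x)
            resid = yv - q @ (q.T @ yv)
            ss += float(resid @ resid)
            df += ok.sum() - np.linalg.matrix_rank(x)
            reps = sub.loc[ok, "rep"].to_numpy()
            grand = yv.mean()
            for r in np.unique(reps):
                m = reps == r
                rep_ss += m.sum() * (yv[m].mean() - grand) ** 2
            rep_df += np.unique(reps).size - 1
        rows.append({
            "trait": trait,
            "error_ms": ss / df if df > 0 else np.nan,
            "error_df": df,
            "rep_ms": rep_ss / rep_df if rep_df > 0 else np.nan,
            "rep_df": rep_df,
        })
    return pd.DataFrame(rows)
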