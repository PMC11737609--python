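"""Trait correlations, hybrid rankings and threshold counts.

These reproduce the summary surfaces a breeder reads first: pairwise
Pearson correlations between traits (on across-environment BLUPs), the
top-n hybrid ranking with group means against the commercial checks, and
counts of hybrids beating a damage-score cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationResult:
    r: pd.DataFrame          # trait x trait Pearson correlations
    p: pd.DataFrame          # two-sided t-based p-values
    n: pd.DataFrame          # pairwise-complete sample sizes

    def critical_r(self, alpha: float, n: int | None = None) -> float:
        """Smallest |r| significant at ``alpha`` for n pairs (t distribution)."""
        if n is None:
            n = int(self.n.to_numpy()[~np.eye(len(self.n), dtype=bool)].min())
        tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
        return float(tcrit / np.sqrt(n - 2 + tcrit**2))


def correlate_traits(blups: pd.DataFrame) -> CorrelationResult:
    """Pairwise-complete Pearson correlations between trait columns.

    ``blups``: entries x traits.  Constant traits (zero variance) yield NaN
    correlations.  Requires at least 3 entries with both traits present for
    a p-value; otherwise NaN.
    """
    traits = list(blups.columns)
    m = len(traits)
    r = pd.DataFrame(np.eye(m), index=traits, columns=traits)
    p = pd.DataFrame(np.nan, index=traits, columns=traits)
    n = pd.DataFrame(0, index=traits, columns=traits)
    for i, a in enumerate(traits):
        n.loc[a, a] = int(blups[a].notna().sum())
        for b in traits[i + 1:]:
            pair = blups[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                continue
            rr, pp = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return CorrelationResult(r=r, p=p, n=n)


@dataclass
class RankingTable:
    """Top-n hybrid ranking with group means.

    ``ranked``: experimental entries sorted by the ranking trait (stable,
    ties broken by entry id); ``group_means``: rows ``checks``,
    ``top`` and ``all`` with one column per trait.
    """

    trait: str
    top_n: int
    ranked: pd.DataFrame
    checks: pd.DataFrame
    group_means: pd.DataFrame


def rank_and_summarize(
    entry_means: pd.DataFrame,
    trait: str,
    top_n: int = 15,
    check_ids: list[str] | None = None,
    ascending: bool = False,
) -> RankingTable:
    """Rank experimental entries by one trait and summarise groups.

    ``entry_means``: entries x traits (wide).  ``ascending=True`` ranks
    damage-type traits where smaller is better.  Group means are plain
    arithmetic means of the member rows, per trait column.
    """
    check_ids = check_ids or []
    unknown = set(check_ids) - set(entry_means.index)
    if unknown:
        raise ValueError(f"unknown check ids: {sorted(unknown)}")
    experimental = entry_means.drop(index=check_ids)
    if top_n > len(experimental):
        raise ValueError(f"top_n={top_n} exceeds {len(experimental)} experimental entries")
    ranked = experimental.sort_values(
        by=[trait], ascending=ascending, kind="mergesort"
    )
    # deterministic tie-break on entry id
    ranked = ranked.loc[
        ranked.assign(_id=ranked.index)
        .sort_values(by=[trait, "_id"], ascending=[ascending, True], kind="mergesort")
        .index
    ]
    checks = entry_means.loc[check_ids]
    groups = {
        "checks": checks.mean(axis=0) if len(checks) else pd.Series(dtype=float),
        "top": ranked.head(top_n).mean(axis=0),
        "all": experimental.mean(axis=0),
    }
    return RankingTable(
        trait=trait, top_n=top_n, ranked=ranked, checks=checks,
        group_means=pd.DataFrame(groups).T,
    )


def count_below(entry_means: pd.DataFrame | pd.Series, trait: str | None = None,
                cutoff: float = 4.0) -> int:
    """Number of entries with trait value strictly below ``cutoff``."""
    if isinstance(entry_means, pd.DataFrame):
        if trait is None:
            raise ValueError("trait required with a DataFrame input")
        values = entry_means[trait]
    else:
        values = entry_means
    return int((values.dropna() < cutoff).sum())
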