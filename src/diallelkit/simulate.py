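"""Synthetic diallel trial generator with known ground-truth genetics.

The generator draws combining-ability effects under the across-environment
diallel model

    y_ij,k = mu + E_k + g_i + g_j + s_ij + (EG)_ik + (EG)_jk + (ES)_ij,k
             + block + e

where ``g`` are general combining abilities (GCA), ``s`` specific combining
abilities (SCA), and the (E*) terms their environment interactions.  Effects
are drawn independently normal with user-set variances and then centred so
the method-4 identifiability constraints hold exactly:

* sum_i g_i = 0,
* for every parent i, sum over crosses containing i of s_ij = 0
  (which implies the overall SCA sum is zero).

Centring is a pure projection of i.i.d. draws onto the constraint space; no
variance rescaling is applied afterwards.  The finite-population accounting
then matches the ANOVA estimand exactly: the expected sum of squares of the
centred effects is df x variance (e.g. (p-1) sigma2_GCA over p parents,
p(p-3)/2 sigma2_SCA over the p(p-1)/2 crosses), which is precisely the
convention under which the expected-mean-squares recipe recovers the
requested variances.  Rescaling the projected draws back to full population
variance would inflate every recovered component by N/df.

Ordinal damage scores (1-9 scales) are produced by rounding a latent
continuous value to the nearest integer and clamping to [1, 9].  Ear rot is
kept continuous and deliberately *not* clamped at zero: adjusted means can
legitimately go slightly negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DiallelDesign, cross_id

#: Trait columns written to plot CSVs, in canonical order.
TRAIT_COLUMNS = (
    "GY", "FD1", "FD2", "FD3", "ED", "ER", "EXHL", "TLGTH",
    "AD", "SD", "ASI", "PH", "EH", "EPP",
)

ORDINAL_TRAITS = frozenset({"FD1", "FD2", "FD3", "ED"})


@dataclass
class TraitSpec:
    """Variance architecture of one trait in the generator.

    Variances are on the plot scale; ``mu`` is the trait grand mean in the
    trait's own units (t/ha for GY, a 1-9 score for damage traits, ...).
    ``env_mask``: if set, the trait is observed only in these environments
    (e.g. exit holes and tunnelling length scored only under artificial
    infestation).
    """

    name: str
    mu: float
    var_gca: float
    var_sca: float
    var_env: float
    var_gca_env: float
    var_sca_env: float
    var_block: float
    var_error: float
    ordinal: bool = False
    check_means: dict[str, float] = field(default_factory=dict)
    env_mask: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for f in ("var_gca", "var_sca", "var_env", "var_gca_env",
                  "var_sca_env", "var_block", "var_error"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.name}: {f} must be >= 0")


@dataclass
class TraitEffects:
    """Realised ground-truth effects for one trait."""

    spec: TraitSpec
    mu: float
    gca: pd.Series                 # parent -> g_i
    sca: pd.Series                 # cross entry id -> s_ij
    env: pd.Series                 # environment -> E_k
    gca_env: pd.DataFrame          # parent x environment -> (EG)_ik
    sca_env: pd.DataFrame          # cross x environment -> (ES)_ij,k

    def genetic_value(self, parent1: str, parent2: str, env: str) -> float:
        c = cross_id(parent1, parent2)
        return (
            self.mu
            + self.env[env]
            + self.gca[parent1]
            + self.gca[parent2]
            + self.sca[c]
            + self.gca_env.loc[parent1, env]
            + self.gca_env.loc[parent2, env]
            + self.sca_env.loc[c, env]
        )


@dataclass
class TrueGenetics:
    """Ground-truth genetic parameters of a simulated diallel study."""

    design: DiallelDesign
    traits: dict[str, TraitEffects]

    def trait_names(self) -> list[str]:
        return list(self.traits)


def _centre_gca(raw: np.ndarray) -> np.ndarray:
    """Centre GCA draws to sum exactly zero (projection, no rescale)."""
    return raw - raw.mean()


def _centre_sca(raw: np.ndarray, pairs: np.ndarray, p: int) -> np.ndarray:
    """Project SCA draws onto the method-4 constraint space.

    Solves for per-parent adjustments c_i such that
    s'_ij = s_ij - c_i - c_j has zero sum over the crosses of every parent;
    this is exactly the removal of the GCA-like component of the draws
    (a projection onto the p(p-3)/2-dimensional SCA space, no rescale).
    """
    row_sums = np.zeros(p)
    np.add.at(row_sums, pairs[:, 0], raw)
    np.add.at(row_sums, pairs[:, 1], raw)
    total = row_sums.sum() / (2 * p - 2)
    c = (row_sums - total) / (p - 2)
    return raw - c[pairs[:, 0]] - c[pairs[:, 1]]


def simulate_genetics(
    design: DiallelDesign,
    var_gca: float,
    var_sca: float,
    var_env: float = 0.0,
    var_gca_env: float = 0.0,
    var_sca_env: float = 0.0,
    seed: int | np.random.Generator = 0,
    *,
    mu: float = 0.0,
    var_block: float = 0.0,
    var_error: float = 0.0,
    trait: str = "GY",
    ordinal: bool = False,
    check_means: dict[str, float] | None = None,
    env_mask: tuple[str, ...] | None = None,
    gca: pd.Series | None = None,
) -> TrueGenetics:
    """Draw ground-truth effects for a single trait.

    All effect classes are independent normal with the stated variances and
    are centred to satisfy the method-4 sum-to-zero constraints exactly.
    With a single environment the (EG) and (ES) terms are identically zero.
    ``gca`` may be supplied (e.g. derived from marker effects) to override
    the random GCA draw; it is centred but not rescaled.

    Reproducible: a fixed integer seed yields identical effects.
    """
    spec = TraitSpec(
        name=trait, mu=mu, var_gca=var_gca, var_sca=var_sca, var_env=var_env,
        var_gca_env=var_gca_env, var_sca_env=var_sca_env,
        var_block=var_block, var_error=var_error, ordinal=ordinal,
        check_means=dict(check_means or {}), env_mask=env_mask,
    )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    p = design.n_parents
    parents = list(design.parents)
    crosses = [cross_id(a, b) for a, b in design.crosses]
    envs = list(design.environments)
    e = len(envs)
    parent_pos = {par: i for i, par in enumerate(parents)}
    pairs = np.array([[parent_pos[a], parent_pos[b]] for a, b in design.crosses])

    if gca is not None:
        g = gca.reindex(parents).to_numpy(dtype=float)
        g = g - g.mean()
    elif var_gca > 0:
        g = _centre_gca(rng.normal(0.0, np.sqrt(var_gca), size=p))
    else:
        g = np.zeros(p)

    if var_sca > 0:
        s = _centre_sca(rng.normal(0.0, np.sqrt(var_sca), size=len(crosses)), pairs, p)
    else:
        s = np.zeros(len(crosses))

    if e > 1 and var_env > 0:
        ek = rng.normal(0.0, np.sqrt(var_env), size=e)
        ek = ek - ek.mean()
    else:
        ek = np.zeros(e)

    if e > 1 and var_gca_env > 0:
        ge = np.column_stack([
            _centre_gca(rng.normal(0.0, np.sqrt(var_gca_env), size=p)) for _ in envs
        ])
    else:
        ge = np.zeros((p, e))

    if e > 1 and var_sca_env > 0:
        se = np.column_stack([
            _centre_sca(rng.normal(0.0, np.sqrt(var_sca_env), size=len(crosses)), pairs, p)
            for _ in envs
        ])
    else:
        se = np.zeros((len(crosses), e))

    eff = TraitEffects(
        spec=spec,
        mu=mu,
        gca=pd.Series(g, index=parents),
        sca=pd.Series(s, index=crosses),
        env=pd.Series(ek, index=envs),
        gca_env=pd.DataFrame(ge, index=parents, columns=envs),
        sca_env=pd.DataFrame(se, index=crosses, columns=envs),
    )
    return TrueGenetics(design=design, traits={trait: eff})


def merge_genetics(*parts: TrueGenetics) -> TrueGenetics:
    """Combine single-trait TrueGenetics objects sharing one design."""
    design = parts[0].design
    traits: dict[str, TraitEffects] = {}
    for part in parts:
        if part.design is not design and part.design != design:
            raise ValueError("all parts must share the same design")
        traits.update(part.traits)
    return TrueGenetics(design=design, traits=traits)


def clamp_score(latent: float | np.ndarray) -> np.ndarray:
    """Round a latent continuous value to the nearest 1-9 ordinal score."""
    return np.clip(np.rint(latent), 1, 9)


def simulate_trial(
    design: DiallelDesign,
    genetics: TrueGenetics,
    seed: int,
) -> pd.DataFrame:
    """Simulate plot-level data for every environment and replicate.

    Returns a tidy DataFrame with one row per plot: columns ``env, rep,
    block, entry, parent1, parent2, is_check`` followed by one column per
    trait.  Block membership is randomised per replicate from ``seed``;
    entries in a replicate are permuted and cut into blocks of
    ``design.block_size`` (last block possibly short).  Checks receive their
    own means plus environment and plot effects but no diallel genetics.

    Deterministic: the same seed yields a byte-identical table.
    """
    if genetics.design.parents != design.parents or genetics.design.crosses != design.crosses:
        raise ValueError("design and genetics describe different diallels")

    rng = np.random.default_rng(seed)
    entries = list(design.entries)
    cross_parents = design.cross_index()
    n_entry = len(entries)
    traits = genetics.trait_names()

    rows: list[dict] = []
    for env in design.environments:
        for rep in range(1, design.reps_per_env + 1):
            order = rng.permutation(n_entry)
            block_of = np.empty(n_entry, dtype=int)
            for pos, idx in enumerate(order):
                block_of[idx] = pos // design.block_size + 1
            n_blocks = int(block_of.max())
            block_effects = {
                t: {
                    b: rng.normal(0.0, np.sqrt(genetics.traits[t].spec.var_block))
                    if genetics.traits[t].spec.var_block > 0 else 0.0
                    for b in range(1, n_blocks + 1)
                }
                for t in traits
            }
            for i, entry in enumerate(entries):
                row: dict = {
                    "env": env,
                    "rep": rep,
                    "block": int(block_of[i]),
                    "entry": entry,
                }
                is_check = entry in design.checks
                if is_check:
                    row["parent1"] = ""
                    row["parent2"] = ""
                else:
                    row["parent1"], row["parent2"] = cross_parents[entry]
                row["is_check"] = is_check
                for t in traits:
                    eff = genetics.traits[t]
                    spec = eff.spec
                    if spec.env_mask is not None and env not in spec.env_mask:
                        row[t] = np.nan
                        continue
                    if is_check:
                        base = spec.check_means.get(entry, spec.mu) + eff.env[env]
                    else:
                        base = eff.genetic_value(row["parent1"], row["parent2"], env)
                    value = base + block_effects[t][int(block_of[i])]
                    if spec.var_error > 0:
                        value += rng.normal(0.0, np.sqrt(spec.var_error))
                    if spec.ordinal:
                        value = float(clamp_score(value))
                    row[t] = value
                rows.append(row)

    cols = ["env", "rep", "block", "entry", "parent1", "parent2", "is_check"] + traits
    return pd.DataFrame(rows, columns=cols)


def default_trait_specs() -> dict[str, TraitSpec]:
    """Trait architectures emulating the motivating FAW diallel study.

    GCA/SCA/interaction and error variances for the nine core traits are the
    published across-environment variance components of the study (plot
    scale); grand means and check means follow its summary tables.
    Environment and block variances are not published and are set to
    field-realistic values (methods note).  EXHL and TLGTH are observed only
    in the artificially infested environment (E1).
    """
    # name: (mu, var_gca, var_sca, var_env, var_gca_env, var_sca_env,
    #        var_block, var_error, ordinal)
    table = {
        "GY":  (5.32, 0.22, 0.27, 1.10, 0.17, 0.39, 0.20, 1.29, False),
        "FD1": (4.17, 0.04, 0.00, 1.20, 0.01, 0.15, 0.05, 0.31, True),
        "FD2": (5.00, 0.03, 0.04, 1.70, 0.04, 0.07, 0.05, 0.33, True),
        "FD3": (4.78, 0.07, 0.04, 0.70, 0.06, 0.15, 0.05, 0.37, True),
        "ED":  (2.31, 0.06, 0.04, 1.50, 0.04, 0.04, 0.05, 0.23, True),
        "ER":  (12.37, 9.00, 7.00, 12.0, 6.00, 10.0, 2.00, 60.0, False),
        "EXHL": (1.2, 0.10, 0.08, 0.00, 0.00, 0.00, 0.02, 0.40, False),
        "TLGTH": (8.0, 4.00, 3.00, 0.00, 0.00, 0.00, 0.50, 12.0, False),
        "AD":  (56.04, 1.29, 0.37, 1.80, 0.03, 0.17, 0.10, 1.30, False),
        "SD":  (57.20, 1.32, 0.45, 2.00, 0.07, 0.56, 0.10, 1.50, False),
        "ASI": (1.16, 0.05, 0.05, 0.20, 0.02, 0.05, 0.02, 0.40, False),
        "PH":  (260.1, 95.77, 80.88, 330.0, 5.80, 107.72, 15.0, 109.31, False),
        "EH":  (130.0, 58.34, 36.65, 120.0, 0.21, 52.87, 8.00, 46.66, False),
        "EPP": (1.02, 0.002, 0.002, 0.005, 0.001, 0.002, 0.001, 0.01, False),
    }
    checks = {
        # published check performance for the eight summary-table traits
        "GY":  {"WE1101": 5.29, "Duma43": 4.40, "DK8031": 3.69, "DH04": 2.97},
        "AD":  {"WE1101": 56.56, "Duma43": 53.53, "DK8031": 55.68, "DH04": 58.01},
        "PH":  {"WE1101": 258.55, "Duma43": 266.79, "DK8031": 260.68, "DH04": 254.36},
        "FD1": {"WE1101": 4.68, "Duma43": 4.41, "DK8031": 4.99, "DH04": 5.03},
        "FD2": {"WE1101": 5.45, "Duma43": 5.58, "DK8031": 6.03, "DH04": 6.32},
        "FD3": {"WE1101": 5.32, "Duma43": 5.55, "DK8031": 5.75, "DH04": 6.07},
        "ED":  {"WE1101": 2.57, "Duma43": 3.85, "DK8031": 4.65, "DH04": 3.31},
        "ER":  {"WE1101": 8.59, "Duma43": 35.99, "DK8031": 50.64, "DH04": 40.83},
    }
    specs = {}
    for name, (mu, vg, vs, ve, vge, vse, vb, verr, ordinal) in table.items():
        specs[name] = TraitSpec(
            name=name, mu=mu, var_gca=vg, var_sca=vs, var_env=ve,
            var_gca_env=vge, var_sca_env=vse, var_block=vb, var_error=verr,
            ordinal=ordinal, check_means=checks.get(name, {}),
            env_mask=("E1",) if name in ("EXHL", "TLGTH") else None,
        )
    return specs


def simulate_study(
    design: DiallelDesign,
    seed: int,
    trait_specs: dict[str, TraitSpec] | None = None,
    marker_gca: dict[str, pd.Series] | None = None,
) -> tuple[TrueGenetics, pd.DataFrame]:
    """Simulate a full multi-trait study: ground truth plus plot data.

    ``marker_gca`` maps trait name -> a parental genetic-value Series (e.g.
    from causal marker effects); the trait's GCA is then that vector centred
    and rescaled to the trait's ``var_gca``, so marker-based prediction has
    recoverable signal for those traits.
    """
    specs = trait_specs or default_trait_specs()
    rng = np.random.default_rng(seed)
    parts = []
    for name, spec in specs.items():
        gca = None
        if marker_gca and name in marker_gca:
            raw = marker_gca[name].reindex(design.parents).to_numpy(dtype=float)
            raw = raw - raw.mean()
            sd = raw.std()
            if sd > 0 and spec.var_gca > 0:
                raw = raw * np.sqrt(spec.var_gca) / sd
            gca = pd.Series(raw, index=list(design.parents))
        parts.append(
            simulate_genetics(
                design,
                spec.var_gca, spec.var_sca, spec.var_env,
                spec.var_gca_env, spec.var_sca_env,
                seed=rng,
                mu=spec.mu, var_block=spec.var_block, var_error=spec.var_error,
                trait=name, ordinal=spec.ordinal, check_means=spec.check_means,
                env_mask=spec.env_mask, gca=gca,
            )
        )
    genetics = merge_genetics(*parts)
    plot_seed = int(rng.integers(2**31 - 1))
    plots = simulate_trial(design, genetics, seed=plot_seed)
    return genetics, plots


def truth_to_dict(genetics: TrueGenetics) -> dict:
    """Ground truth as a JSON-serialisable structure (sidecar file)."""
    out: dict = {"parents": list(genetics.design.parents), "traits": {}}
    for name, eff in genetics.traits.items():
        out["traits"][name] = {
            "mu": eff.mu,
            "gca": {k: float(v) for k, v in eff.gca.items()},
            "sca": {k: float(v) for k, v in eff.sca.items()},
            "env": {k: float(v) for k, v in eff.env.items()},
        }
    return out
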