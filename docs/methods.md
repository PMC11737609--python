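# Methods

## The model

`diallelkit` analyses half-diallel trials under the across-environment
combining-ability model

```
y_ij,k = mu + E_k + g_i + g_j + s_ij + (EG)_ik + (EG)_jk + (ES)_ij,k + b + e
```

where `g_i` is the general combining ability (GCA) of parent *i*, `s_ij`
the specific combining ability (SCA) of cross *(i, j)*, `E_k` an
environment effect, the `(E·)` terms environment interactions, `b` an
incomplete-block effect and `e` plot error.  Griffing's method 4 covers
the case analysed here: only the `p(p-1)/2` F1 crosses are evaluated — no
parents, no reciprocals.  Identifiability comes from the usual sum-to-zero
constraints: `sum_i g_i = 0`, and for every parent `i`,
`sum_{j != i} s_ij = 0`.

### Effect estimation

On a balanced set of per-cross means `x_ij` the closed forms are

```
mu   = 2 x.. / (p (p - 1))
g_i  = [p x_i. - 2 x..] / [p (p - 2)]
s_ij = x_ij - mu - g_i - g_j
```

with `x_i.` the sum over crosses containing parent *i*.  With missing
crosses the same effects are estimated by least squares under the sum-zero
constraint (reduced parametrisation, `numpy.linalg.lstsq`); the test suite
verifies that the balanced closed forms coincide with the constrained
least-squares solution to 1e-10 on random diallels of 4-8 parents.

Standard errors use the balanced method-4 sampling variances
`Var(g_i) = (p-1)/(p(p-2)) * s2_eff` and
`Var(s_ij) = (p-3)/(p-1) * s2_eff`, where `s2_eff` is the error stratum on
the across-environment entry-mean scale: the corresponding environment
interaction mean square divided by `r e` (plot error within a single
environment).  Both coefficients are verified numerically against the
squared norm of the estimator's linear coefficients.  Effects are tested
with two-sided *t* statistics on the stratum's degrees of freedom; no
multiplicity correction is applied.

### ANOVA and error strata

Combining-ability sums of squares are computed on entry means and
multiplied by the replicate count `r`, so mean squares sit on the
plot-equivalent scale conventional for multi-environment diallel reports.
Equivalently, interaction rows are tested against the pooled plot error
mean square divided by `r` on the entry-mean scale; the two conventions
give identical F ratios.  Test strata: hybrids and environments against
hybrid-by-environment; GCA and SCA against their environment interactions;
every interaction row against the pooled intra-block plot error (from the
per-environment entry + replicate residuals).  Degrees of freedom follow
the method-4 identities (`GCA: p-1`, `SCA: p(p-3)/2`, hybrids
`p(p-1)/2 - 1`, and `(e-1)` times each for interactions).

### Variance components and ratios

The expected-mean-squares solution (entry-mean basis, rescaled by `r e`):

```
s2_SCA   = (MS_SCA - MS_SCAxE) / (r e)
s2_GCA   = [(MS_GCA - MS_GCAxE) - (MS_SCA - MS_SCAxE)] / (r e (p - 2))
s2_GCAxE = (MS_GCAxE - MS_SCAxE) / (r (p - 2))
s2_SCAxE = (MS_SCAxE - s2_e) / r
```

Negative solutions clamp to zero (and are logged).  Derived rows:
`s2_A = 2 s2_GCA`, `s2_D = s2_SCA`, `s2_P = s2_A + s2_D + s2_e`; the Baker
ratio `2 s2_GCA / (2 s2_GCA + s2_SCA)` measures how predictable hybrids
are from parental GCA alone; broad-sense entry-mean heritability is
`H2 = s2_G / (s2_G + s2_GxE/e + s2_e/(r e))` from the hybrid rows, clamped
to [0, 1].

This recipe reproduces, cell for cell to the printed two decimals, the
published GCA/SCA/interaction variance components of the motivating
21-parent fall-armyworm study from its printed mean squares (r = 2,
e = 2) — the package's arithmetic anchor, exercised by
`tests/test_acceptance.py` and `scripts/acceptance.py`.  Two published
inconsistencies are handled explicitly rather than smoothed away:

* the study's `s2_e` row (a separate REML estimate, e.g. 1.29 for grain
  yield) differs slightly from its ANOVA error mean square (1.23);
  `variance_components` therefore accepts an explicit `sigma2_e` override,
  and the published phenotypic variances only reproduce with the published
  `s2_e` (both values are exposed);
* the published heritabilities are close to, but not exactly, the
  entry-mean formula applied to the printed mean squares (0.86 computed vs
  0.84 printed for days to anthesis) — treated as REML/rounding
  differences and not asserted.

## Entry means (two-stage analysis)

Stage one fits, per environment and trait, the lattice model with entries
fixed and replicates and blocks-within-replicates random (BLUEs), or
entries random (BLUPs, shrunken toward the grand mean).  Across
environments the model adds random environment, replicate-within-
environment and entry-by-environment terms.  Variance components are
estimated by EM-REML on Henderson's mixed-model equations (dense Cholesky;
iteration cap 500, relative tolerance 1e-8; components collapsing toward
zero are frozen at zero).  EM guarantees non-negative components and a
monotone restricted likelihood, which the test suite asserts.  The MME
route is checked against a brute-force dense GLS solve (explicit `V`
inverse) at fixed variance components to 1e-8.

The diallel stage consumes per-environment BLUEs; across-environment entry
means for effect estimation are the averages of the per-environment BLUEs
(identical to the joint GLS solution on balanced data).  Across-environment
BLUPs feed the correlation and ranking surfaces.

Outlier screening flags plots with |internally studentised residual| > 3.5
(default) from a per-environment entry + replicate fixed-effects fit.
With two replicates the residuals of an entry come in ± pairs, so a flag
removes both plots of that entry in that environment; the resulting
missing entry-mean cells are restored by the classic missing-plot
technique (additive entry + environment least-squares fit) before the
balanced ANOVA.  The ANOVA degrees of freedom are not reduced for imputed
cells; with the handful of cells involved the effect is negligible.

## Prediction of hybrid performance

**GCA-based leave-one-hybrid-out.**  For each cross, `mu` and the GCA
vector are re-estimated from all other crosses and the held-out hybrid is
predicted as `mu + g_i + g_j`.  Accuracy is the Pearson correlation over
all held-out pairs.  In the noise-free purely additive limit this
correlation is exactly 1 (asserted to 1e-9).  Under a pure-noise null the
statistic carries a small negative bias (measured -0.03 over 100 seeds,
sd 0.10) because each prediction shares the training mean of the remaining
crosses; "centred at zero" is therefore asserted as |mean r| < 0.05, five
Monte-Carlo SEs wide and far below any signal run.

**Marker-based GBLUP.**  Hybrid genotypes are parental means (only
inbred parents are genotyped); kinship is the VanRaden centred
cross-product `K = W W' / sum 2 p_m (1 - p_m)`.  The model
`y = 1 mu + u + e`, `u ~ N(0, K s2_u)` is fitted by REML on each training
fold via the eigendecomposition of `K`, reducing the restricted likelihood
to a one-dimensional optimisation in `log(s2_e/s2_u)`; held-out hybrids
are predicted through their kinship with the training set.  This
GBLUP/ridge formulation is the deterministic equivalent of a Bayesian
ridge fit (the posterior mean coincides with BLUP under matched
hyperparameters) and was chosen over a sampler for reproducibility and
speed.  Folds are a seeded permutation of hybrids; both parents of a
held-out hybrid may appear in training crosses (T2-style CV).

**Accuracy metric.**  The reported `r` for k-fold CV is the within-fold
Pearson correlation averaged over folds — the conventional accuracy in
genomic prediction.  The correlation over the concatenated held-out pairs
is also reported (`r_pooled`) but is *not* used as the headline number
because it is structurally biased downward under weak signal: each fold's
training mean is anti-correlated with the held-out fold's observations
(measured -0.108 +/- 0.009 under a pure-noise null, versus +0.006 +/- 0.010
for the per-fold average).

## The synthetic study

The generator reproduces the study conditions: 21 inbred parents, all 210
F1 crosses, four commercial checks, two environments, two replicates,
incomplete blocks of 10 plots randomised per replicate.  Fourteen trait
columns are simulated; the nine traits with published variance components
(FD1-FD3, ED, GY, AD, SD, PH, EH) use exactly those components on the plot
scale, with grand means and check means from the published summary tables.
Environment and block variances are not published: environment variances
were set so that environment mean squares are of the published order of
magnitude (e.g. 1.1 (t/ha)^2 for grain yield), block variance to roughly
15% of plot error — ordinary magnitudes for tropical maize yield trials —
and ear rot (not in the published component table) was given components
yielding a heritability in the published 0.25-0.33 band.  Exit holes and
tunnelling length are observed only in the artificially infested
environment (E1), mirroring the study's recording pattern.

Design choices in the generator:

* **Distributions.**  All effect classes are independent normal with the
  stated variances — the standard quantitative-genetics assumption behind
  the ANOVA expectations; the study reports only variances.
* **Exact constraints, projection convention.**  Draws are centred by
  projection onto the constraint space and *not* rescaled afterwards.
  The expected sum of squares of the centred effects is then
  df x variance — exactly the estimand of the expected-mean-squares
  recipe, so the ANOVA chain recovers the requested components (verified
  over 200 simulations at the published grain-yield values, within 3
  Monte-Carlo SEs).  Rescaling to full population variance would inflate
  every recovered component by N/df.  One inherent residual remains:
  with truth confined to the constraint space there is no SCA leakage
  into the GCA stratum, so the recipe's leakage correction biases
  `s2_GCA` by `-s2_SCA/(p-2)` (about -0.014 at the grain-yield values) —
  well inside the Monte-Carlo tolerance and documented here rather than
  hidden by a compensating tweak.
* **Ordinal scores.**  A latent Gaussian value is rounded to the nearest
  integer and clamped to [1, 9].  Residual diagnostics of the resulting
  scores remain symmetric, matching how the study analysed scores
  untransformed.  Ear rot is a continuous adjusted percentage and may go
  slightly negative, as in the published tables.
* **Markers.**  Per-SNP alt-allele frequencies are uniform in
  `maf_range`; inbred genotypes are Bernoulli homozygotes (0/2).  The
  generator enforces its constraints on the *realised* panel: SNPs are
  resampled until the realised MAF lies within range, and per-SNP missing
  calls are capped at `ceil(n x missing_rate)`, so QC at looser
  thresholds retains every SNP (generator-filter consistency is a test).
  A chosen causal subset carries i.i.d. normal additive effects; the
  implied parental values can be injected as a trait's GCA (rescaled to
  the trait's GCA variance), giving marker-based prediction recoverable
  signal.  By default grain yield is marker-driven.
* **Checks.**  Simulated as extra entries with their own published means
  plus environment and plot effects, and excluded from all diallel
  computations.

What the generator does **not** emulate: spatial field trend beyond
i.i.d. block effects, insect population dynamics, trait-specific
missing-data mechanisms other than the environment mask, selection or
multi-year structure.  Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to field
pathologies outside it.

## Problem sizes and numerics

Default problem sizes: the full 21-parent design (840 experimental plots
plus checks), 2,000 SNPs (about 200 causal), fivefold CV; simulation
batteries use 100-200 replicates with the fast arithmetic entry-mean path,
which equals the BLUE when block and replicate variances are zero.  The
complete pipeline runs in a few minutes on one CPU and is byte-identical
under a fixed seed (all randomness flows from `numpy.random.default_rng`
seeded per stage).

Numerical choices: EM-REML cap 500 iterations, relative tolerance 1e-8,
variance floor 1e-12 with freezing of collapsing components; GBLUP ridge
1e-8 on the kinship diagonal; least-squares pivot tolerance 1e-12;
ranking tie-break on entry id (stable mergesort); Pearson correlations are
pairwise-complete and undefined (reported missing) for constant traits.

## Known limitations

* Single-environment diallels cannot separate combining-ability variance
  from its environment interaction; `variance_components` refuses them.
* The EMS recipe assumes a balanced cross set; missing crosses are
  handled for effect estimation but not for the variance-component ANOVA
  (beyond the missing-cell imputation above).
* Heterogeneous error variances per environment and spatial adjustments
  are out of scope; the pooled error assumes exchangeable plots.
* The published prediction correlations of the motivating study (e.g.
  0.79 GCA-based and 0.96 marker-based for grain yield) depend on its raw
  data, which are not public; the package's simulations reproduce the
  qualitative pattern (marker-based at or above GCA-based for
  marker-driven yield-like traits), not those exact numbers.
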