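# diallelkit

Combining-ability analysis and hybrid prediction for half-diallel maize
trials, built around the breeding problem of native resistance to fall
armyworm (*Spodoptera frugiperda*): given 21 inbred parents crossed into
all 210 F1 hybrids and evaluated under FAW infestation in two
environments, which parents transmit resistance and yield, and how well
can untested hybrids be predicted from parental data alone?

The package is for quantitative geneticists and maize breeders working
with diallel mating designs.  It implements:

* **Griffing model-1 / method-4 analysis** — GCA/SCA effects with the
  balanced closed forms (`mu = 2x../(p(p-1))`,
  `g_i = [p x_i. - 2 x..]/[p(p-2)]`, `s_ij = x_ij - mu - g_i - g_j`) or
  constrained least squares with missing crosses; the across-environment
  ANOVA with its method-4 error strata; the expected-mean-squares solution
  for `s2_GCA, s2_SCA, s2_GCAxE, s2_SCAxE`; derived `s2_A = 2 s2_GCA`,
  `s2_D = s2_SCA`, `s2_P`; the Baker ratio
  `2 s2_GCA/(2 s2_GCA + s2_SCA)`; entry-mean heritability; and *t* tests
  of every effect.
* **Entry means from alpha-lattice plot data** — per-environment BLUEs and
  across-environment BLUPs by EM-REML on Henderson's mixed-model
  equations, with studentised-residual outlier screening.
* **Hybrid prediction** — GCA-based leave-one-hybrid-out cross-validation
  and marker-based GBLUP (VanRaden kinship from parental-mean hybrid
  genotypes, REML variance ratio, fivefold CV) with SNP QC at
  MAF > 0.05 and missingness < 10%.
* **A synthetic study generator** — full diallel trials (phenotypes on the
  published trait scales, ordinal 1-9 damage scores, commercial checks,
  SNP panels) with known ground truth, so the whole chain is testable
  without any external data.
* **Summary surfaces** — hybrid rankings against checks, trait
  correlations on BLUPs, damage-score threshold counts.

The layout follows the analysis: `src/diallelkit/` holds the library,
`analysis/01_simulate.py` … `analysis/05_summarize.py` are thin numbered
drivers that run the study end to end and write tables under `results/`,
and `diallelkit` is a CLI with `simulate / means / diallel / predict /
summarize` subcommands for file-based use.

## Worked example

A study-sized simulated diallel at the published grain-yield variance
components, analysed on entry means:

```python
from diallelkit import (make_design, simulate_genetics, simulate_trial,
                        diallel_anova, variance_components, genetic_ratios)
from diallelkit.trial_means import arithmetic_entry_means, pooled_error

design = make_design(p=21, n_env=2, n_rep=2, block_size=10)
gen = simulate_genetics(design, var_gca=0.22, var_sca=0.27, var_env=1.1,
                        var_gca_env=0.17, var_sca_env=0.39, seed=7,
                        mu=5.32, var_error=1.29)
plots = simulate_trial(design, gen, seed=8)          # 210 crosses, 840 plots

wide = arithmetic_entry_means(plots).pivot_table(
    index="entry", columns="env", values="value")
err = pooled_error(plots)
anova = diallel_anova(wide, design, n_rep=2,
                      error_ms=float(err["error_ms"][0]),
                      error_df=float(err["error_df"][0]))
print(anova.table.round(2))
vc = variance_components(anova, trait="GY")
gr = genetic_ratios(vc, anova)
print(f"Baker ratio {gr.baker_ratio:.2f}, H2 {gr.heritability:.2f}")
```

prints

```
                df      ms       F     p denominator
Environment    1.0  263.21  108.33  0.00         HxE
Hybrids      209.0    4.06    1.67  0.00         HxE
GCA           20.0   17.07    2.08  0.06       GCAxE
SCA          189.0    2.68    1.48  0.00       SCAxE
HxE          209.0    2.43    1.89  0.00       Error
GCAxE         20.0    8.22    6.37  0.00       Error
SCAxE        189.0    1.82    1.41  0.00       Error
Error        418.0    1.29     NaN   NaN
Baker ratio 0.49, H2 0.40
```

Reading it: the degrees of freedom are the method-4 identities for 21
parents (GCA 20, SCA 189, hybrids 209); GCA and SCA are tested against
their environment interactions, interactions against the pooled plot
error.  This particular realisation estimates `s2_GCA = 0.11` and
`s2_SCA = 0.22` (truth 0.22/0.27 — single-trial estimates of GCA variance
lean on only 20 df, which is exactly why the test suite checks recovery
over 200 simulations rather than one).  A Baker ratio near 0.5 says GCA
and SCA matter about equally for yield, so marker data should help beyond
parental GCA — the pattern the prediction stage probes.

The full pipeline (simulate → means → diallel → predict → summarise) is

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_entry_means.py
python analysis/03_combining_ability.py
python analysis/04_predict.py
python analysis/05_summarize.py
```

or, equivalently, `diallelkit simulate|means|diallel|predict|summarize`
on your own CSV/HapMap/VCF files.

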