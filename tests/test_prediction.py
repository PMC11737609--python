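import numpy as np
import pandas as pd
import pytest

from diallelkit import make_design, simulate_genetics
from diallelkit.design import cross_id
from diallelkit.griffing import fit_gca_least_squares
from diallelkit.markers import (filter_markers, grm, parental_genetic_values,
                                simulate_markers)
from diallelkit.prediction import gblup_cv, kfold_assign, loo_gca_predict


def true_means(design, genetics, env="E1"):
    eff = next(iter(genetics.traits.values()))
    return pd.Series({cross_id(a, b): eff.genetic_value(a, b, env)
                      for a, b in design.crosses})


@pytest.fixture(scope="module")
def diallel21():
    return make_design(21, n_env=1, n_rep=2)


@pytest.fixture(scope="module")
def kinship21(diallel21):
    mk, _ = simulate_markers(list(diallel21.parents), 500, (0.1, 0.5),
                             missing_rate=0.0, seed=3)
    return grm(filter_markers(mk).hybrid_matrix(list(diallel21.crosses)))


class TestLooGca:
    def test_noise_free_additive_limit_r_is_one(self):
        d = make_design(6, 1, 2)
        gen = simulate_genetics(d, 0.5, 0.0, seed=7, mu=10.0)
        rep = loo_gca_predict(true_means(d, gen), d)
        assert rep.r == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(rep.table["observed"], rep.table["predicted"], atol=1e-9)

    def test_matches_brute_force_refit_per_deletion(self):
        d = make_design(6, 1, 2)
        rng = np.random.default_rng(4)
        means = pd.Series(rng.normal(10, 2, d.n_crosses),
                          index=[cross_id(a, b) for a, b in d.crosses])
        rep = loo_gca_predict(means, d)
        cp = d.cross_index()
        for c in means.index:
            mu, g = fit_gca_least_squares(means.drop(c), list(d.parents), cp)
            a, b = cp[c]
            assert rep.table.loc[c, "predicted"] == pytest.approx(
                mu + g[a] + g[b], abs=1e-10)

    def test_invariant_to_constant_shift(self, diallel21):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(5, 1, 210),
                      index=[cross_id(a, b) for a, b in diallel21.crosses])
        r1 = loo_gca_predict(y, diallel21).r
        r2 = loo_gca_predict(y + 100.0, diallel21).r
        assert r1 == pytest.approx(r2, abs=1e-10)

    def test_signal_monotonicity(self, diallel21):
        """Mean r under the study's GY variance ratio lies strictly between
        the pure-SCA (no signal) and pure-GCA (full signal) reference runs."""
        def mean_r(var_gca, var_sca, var_entry_noise, n_sim=30, base=0):
            rs = []
            for s in range(n_sim):
                gen = simulate_genetics(diallel21, var_gca, var_sca,
                                        seed=base + s, mu=5.3)
                y = true_means(diallel21, gen)
                rng = np.random.default_rng(7000 + base + s)
                y = y + rng.normal(0, np.sqrt(var_entry_noise), len(y))
                rs.append(loo_gca_predict(y, diallel21).r)
            return float(np.mean(rs))

        noise = 1.23 / 4  # entry-mean error at the study's pooled error, r*e=4
        r_mixed = mean_r(0.22, 0.27, noise, base=100)
        r_pure_gca = mean_r(0.22, 0.0, noise, base=200)
        r_no_gca = mean_r(0.0, 0.27, noise, base=300)
        assert r_no_gca < r_mixed < r_pure_gca

    def test_small_parent_set_flags_missing(self):
        d = make_design(4, 1, 2)
        rng = np.random.default_rng(6)
        means = pd.Series(rng.normal(10, 1, 6),
                          index=[cross_id(a, b) for a, b in d.crosses])
        # with P01/P02 absent, P01 and P02 have only 2 crosses each; deleting
        # any of their crosses drops them below 2 -> flagged missing, while
        # P03/P04 (both parents still at 2 after deletion) stays predictable
        rep = loo_gca_predict(means.drop("P01/P02"), d)
        involving_12 = [c for c in rep.table.index if "P01" in c or "P02" in c]
        assert rep.table.loc[involving_12, "predicted"].isna().all()
        assert not np.isnan(rep.table.loc["P03/P04", "predicted"])


class TestGblup:
    def test_high_heritability_limit(self, diallel21, kinship21):
        mk, eff = simulate_markers(list(diallel21.parents), 500, (0.1, 0.5),
                                   missing_rate=0.0, n_causal=100, seed=3)
        pv = parental_genetic_values(mk, eff)
        gen = simulate_genetics(diallel21, 1.0, 0.0, seed=9, gca=pv)
        y = true_means(diallel21, gen)
        rep = gblup_cv(y, kinship21, k_folds=5, seed=11)
        assert rep.r > 0.95

    def test_determinism_fixed_seed(self, diallel21, kinship21):
        rng = np.random.default_rng(8)
        y = pd.Series(rng.normal(size=210),
                      index=[cross_id(a, b) for a, b in diallel21.crosses])
        rep1 = gblup_cv(y, kinship21, 5, seed=13)
        rep2 = gblup_cv(y, kinship21, 5, seed=13)
        assert rep1.r == rep2.r
        assert (rep1.table["fold"] == rep2.table["fold"]).all()
        rep3 = gblup_cv(y, kinship21, 5, seed=14)
        assert (rep3.table["fold"] != rep1.table["fold"]).any()

    def test_linearity_in_y(self, diallel21, kinship21):
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=210),
                      index=[cross_id(a, b) for a, b in diallel21.crosses])
        p1 = gblup_cv(y, kinship21, 5, seed=15).table["predicted"]
        p2 = gblup_cv(2 * y, kinship21, 5, seed=15).table["predicted"]
        assert np.allclose(p2 - p2.mean(), 2 * (p1 - p1.mean()), atol=1e-6)

    def test_folds_partition_all_hybrids(self):
        folds = kfold_assign(210, 5, seed=17)
        assert len(folds) == 210
        counts = np.bincount(folds, minlength=5)
        assert counts.sum() == 210
        assert counts.min() == counts.max() == 42

    def test_k_too_small_rejected(self, diallel21, kinship21):
        y = pd.Series(0.0, index=kinship21.index)
        with pytest.raises(ValueError):
            gblup_cv(y, kinship21, k_folds=1, seed=1)

    def test_accuracy_increases_with_marker_signal(self, diallel21, kinship21):
        """Average accuracy rises with the marker-additive variance share."""
        mk, eff = simulate_markers(list(diallel21.parents), 500, (0.1, 0.5),
                                   missing_rate=0.0, n_causal=100, seed=3)
        pv = parental_genetic_values(mk, eff)

        def mean_r(share, n_sim=10):
            rs = []
            for s in range(n_sim):
                gen = simulate_genetics(diallel21, 1.0, 0.0, seed=60 + s, gca=pv)
                y = true_means(diallel21, gen)
                y = (y - y.mean()) * np.sqrt(share)
                rng = np.random.default_rng(80 + s)
                y = y + rng.normal(0, np.sqrt(1 - share), len(y))
                rs.append(gblup_cv(y, kinship21, 5, seed=s).r)
            return float(np.mean(rs))

        assert mean_r(0.2) < mean_r(0.6) < mean_r(0.95)
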