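import numpy as np
import pandas as pd
import pytest

from diallelkit import (diallel_anova, effect_tests, genetic_ratios,
                        griffing_effects, make_design, simulate_genetics,
                        simulate_trial, variance_components)
from diallelkit.datasets import (reference_gca_gy, reference_mean_squares,
                                 reference_sigma2_e)
from diallelkit.design import cross_id
from diallelkit.griffing import AnovaTable, baker_ratio, impute_missing_cells
from diallelkit.trial_means import arithmetic_entry_means, pooled_error


def cross_series(design, values):
    return pd.Series(values, index=[cross_id(a, b) for a, b in design.crosses])


def brute_force_constrained_ols(means, design):
    """Independent oracle: solve min ||x - mu - g_i - g_j - s_ij|| with
    sum-zero constraints via explicit Lagrange system on the full design."""
    parents = list(design.parents)
    p = len(parents)
    pos = {par: i for i, par in enumerate(parents)}
    crosses = [c for c in means.index]
    cp = design.cross_index()
    n = len(crosses)
    # parameters: mu, g (p)
    a = np.zeros((n, 1 + p))
    for r, c in enumerate(crosses):
        i, j = (pos[x] for x in cp[c])
        a[r, 0] = 1.0
        a[r, 1 + i] = 1.0
        a[r, 1 + j] = 1.0
    # constraint sum g = 0 via Lagrange
    kkt = np.zeros((1 + p + 1, 1 + p + 1))
    kkt[: 1 + p, : 1 + p] = a.T @ a
    kkt[1 + p, 1: 1 + p] = 1.0
    kkt[1: 1 + p, 1 + p] = 1.0
    rhs = np.append(a.T @ means.to_numpy(), 0.0)
    sol = np.linalg.solve(kkt, rhs)
    mu, g = sol[0], pd.Series(sol[1: 1 + p], index=parents)
    s = pd.Series({c: means[c] - mu - g[cp[c][0]] - g[cp[c][1]] for c in crosses})
    return mu, g, s


class TestGriffingEffects:
    def test_constant_means_give_zero_effects(self):
        d = make_design(4, 1, 2)
        res = griffing_effects(cross_series(d, [10.0] * 6), d)
        assert res.mu == pytest.approx(10.0)
        assert np.allclose(res.gca["estimate"], 0.0)
        assert np.allclose(res.sca["estimate"], 0.0)

    def test_p4_concrete_equals_constrained_ols_oracle(self):
        d = make_design(4, 1, 2)
        means = cross_series(d, [10.0, 12.0, 14.0, 11.0, 13.0, 12.0])
        res = griffing_effects(means, d)
        mu, g, s = brute_force_constrained_ols(means, d)
        assert res.mu == pytest.approx(mu, abs=1e-10)
        assert np.allclose(res.gca["estimate"], g, atol=1e-10)
        assert np.allclose(res.sca["estimate"], s[res.sca.index], atol=1e-10)

    @pytest.mark.parametrize("p", [4, 5, 6, 7, 8])
    def test_balanced_closed_forms_match_oracle(self, p):
        d = make_design(p, 1, 2)
        rng = np.random.default_rng(p)
        means = cross_series(d, rng.normal(20, 3, d.n_crosses))
        res = griffing_effects(means, d)
        mu, g, s = brute_force_constrained_ols(means, d)
        assert res.mu == pytest.approx(mu, abs=1e-10)
        assert np.allclose(res.gca["estimate"], g, atol=1e-10)

    @pytest.mark.parametrize("p", [5, 7])
    def test_zero_sum_and_reconstruction_invariants(self, p):
        d = make_design(p, 1, 2)
        rng = np.random.default_rng(100 + p)
        means = cross_series(d, rng.normal(0, 5, d.n_crosses))
        res = griffing_effects(means, d)
        assert abs(res.gca["estimate"].sum()) < 1e-10
        mat = res.sca_matrix()
        assert np.nanmax(np.abs(np.nansum(mat.to_numpy(), axis=1))) < 1e-10
        for c, row in res.sca.iterrows():
            recon = (res.mu + res.gca.loc[row["parent1"], "estimate"]
                     + res.gca.loc[row["parent2"], "estimate"] + row["estimate"])
            assert recon == pytest.approx(means[c], abs=1e-10)

    def test_missing_cross_path_matches_subset_ols(self):
        d = make_design(6, 1, 2)
        rng = np.random.default_rng(9)
        means = cross_series(d, rng.normal(10, 2, 15)).drop("P01/P02")
        res = griffing_effects(means, d)
        mu, g, _ = brute_force_constrained_ols(means, d)
        assert res.mu == pytest.approx(mu, abs=1e-8)
        assert np.allclose(res.gca["estimate"], g, atol=1e-8)
        assert np.isnan(res.sca.loc["P01/P02", "estimate"])

    def test_published_gca_effects_sum_to_zero(self):
        """The printed grain-yield GCA column of the study sums to 0.00."""
        gca = reference_gca_gy()
        assert len(gca) == 21
        assert abs(gca.sum()) < 0.005


class TestDiallelAnova:
    def test_df_identities_study_layout(self):
        d = make_design(21, 2, 2)
        gen = simulate_genetics(d, 0.22, 0.27, 1.0, 0.17, 0.39, seed=71,
                                mu=5.3, var_error=1.29)
        plots = simulate_trial(d, gen, seed=72)
        wide = arithmetic_entry_means(plots).pivot_table(
            index="entry", columns="env", values="value")
        pe = pooled_error(plots)
        an = diallel_anova(wide, d, 2, float(pe["error_ms"][0]),
                           float(pe["error_df"][0]))
        assert an.df("GCA") == 20
        assert an.df("SCA") == 189
        assert an.df("Hybrids") == 209
        assert an.df("GCAxE") == 20
        assert an.df("SCAxE") == 189
        assert an.df("HxE") == 209
        assert an.table.loc["GCA", "denominator"] == "GCAxE"
        assert an.table.loc["Hybrids", "denominator"] == "HxE"

    def test_ss_partition(self):
        d = make_design(7, 2, 2)
        gen = simulate_genetics(d, 0.5, 0.3, 1.0, 0.2, 0.2, seed=73,
                                mu=10.0, var_error=1.0)
        plots = simulate_trial(d, gen, seed=74)
        wide = arithmetic_entry_means(plots).pivot_table(
            index="entry", columns="env", values="value")
        pe = pooled_error(plots)
        an = diallel_anova(wide, d, 2, float(pe["error_ms"][0]),
                           float(pe["error_df"][0]))
        t = an.table
        assert (t.loc["GCA", "ms"] * t.loc["GCA", "df"]
                + t.loc["SCA", "ms"] * t.loc["SCA", "df"]) == pytest.approx(
            t.loc["Hybrids", "ms"] * t.loc["Hybrids", "df"], rel=1e-8)
        assert (t.loc["GCAxE", "ms"] * t.loc["GCAxE", "df"]
                + t.loc["SCAxE", "ms"] * t.loc["SCAxE", "df"]) == pytest.approx(
            t.loc["HxE", "ms"] * t.loc["HxE", "df"], rel=1e-8)

    def test_null_f_statistics_calibrated(self):
        """With no genetic variance the GCA F ratio follows its null F law:
        the mean matches d2/(d2-2) and the 5% rejection rate its binomial
        interval over 200 simulations."""
        d = make_design(8, 2, 2)
        fs, rejections = [], 0
        n_sim = 200
        for s in range(n_sim):
            gen = simulate_genetics(d, 0.0, 0.0, 1.0, 0.0, 0.0,
                                    seed=1000 + s, mu=5.0, var_error=1.0)
            plots = simulate_trial(d, gen, seed=3000 + s)
            wide = arithmetic_entry_means(plots).pivot_table(
                index="entry", columns="env", values="value")
            pe = pooled_error(plots)
            an = diallel_anova(wide, d, 2, float(pe["error_ms"][0]),
                               float(pe["error_df"][0]))
            fs.append(an.table.loc["GCA", "F"])
            rejections += an.table.loc["GCA", "p"] < 0.05
        d2 = float(an.df("GCAxE"))
        expected = d2 / (d2 - 2)  # null mean of an F variate
        mc_se = np.std(fs) / np.sqrt(n_sim)
        assert abs(np.mean(fs) - expected) < 3 * mc_se
        # binomial 99% envelope around 0.05 with n=200
        assert abs(rejections / n_sim - 0.05) < 2.6 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_single_env_table(self):
        d = make_design(6, 1, 2)
        gen = simulate_genetics(d, 0.5, 0.3, seed=75, mu=10.0, var_error=1.0)
        plots = simulate_trial(d, gen, seed=76)
        wide = arithmetic_entry_means(plots).pivot_table(
            index="entry", columns="env", values="value")
        pe = pooled_error(plots)
        an = diallel_anova(wide, d, 2, float(pe["error_ms"][0]),
                           float(pe["error_df"][0]))
        assert an.single_env
        assert "GCAxE" not in an.table.index
        assert an.table.loc["GCA", "denominator"] == "SCA"

    def test_missing_cell_imputation_additive_exact(self):
        # additive table: imputation restores the removed cell exactly
        wide = pd.DataFrame(
            {"E1": [10.0, 12.0, 14.0], "E2": [11.0, 13.0, 15.0]},
            index=["a", "b", "c"],
        )
        holed = wide.copy()
        holed.loc["b", "E2"] = np.nan
        filled = impute_missing_cells(holed)
        assert filled.loc["b", "E2"] == pytest.approx(13.0)


@pytest.fixture(scope="module")
def published():
    ms = reference_mean_squares()

    def anova_for(trait):
        tab = ms[["df", trait]].rename(columns={trait: "ms"}).astype(float)
        return AnovaTable(table=tab, p=21, n_env=2, n_rep=2)

    return anova_for


class TestVarianceComponents:
    def test_reconstructs_published_components_ph(self, published):
        vc = variance_components(published("PH"),
                                 sigma2_e=reference_sigma2_e()["PH"])
        assert vc.sigma2_gca == pytest.approx(95.77, abs=0.005)
        assert vc.sigma2_sca == pytest.approx(80.88, abs=0.005)
        assert vc.sigma2_gca_env == pytest.approx(5.80, abs=0.005)
        assert vc.sigma2_sca_env == pytest.approx(107.72, abs=0.005)
        assert vc.sigma2_p == pytest.approx(381.72, abs=0.01)

    def test_reconstructs_published_components_ad(self, published):
        vc = variance_components(published("AD"),
                                 sigma2_e=reference_sigma2_e()["AD"])
        assert vc.sigma2_gca == pytest.approx(1.29, abs=0.005)
        assert vc.sigma2_sca == pytest.approx(0.37, abs=0.005)
        assert vc.sigma2_a == pytest.approx(2.58, abs=0.01)

    def test_negative_component_clamped(self, published):
        # FD1: MS_SCA 0.53 < MS_SCAxE 0.61 -> sigma2_SCA clamps to 0
        vc = variance_components(published("FD1"),
                                 sigma2_e=reference_sigma2_e()["FD1"])
        assert vc.sigma2_sca == 0.0
        assert "sigma2_SCA" in vc.clamped

    def test_equal_mean_squares_give_zero_components(self):
        tab = pd.DataFrame(
            {"df": [209, 20, 189, 209, 20, 189, 225],
             "ms": [2.0] * 7},
            index=["Hybrids", "GCA", "SCA", "HxE", "GCAxE", "SCAxE", "Error"],
        )
        vc = variance_components(AnovaTable(tab, p=21, n_env=2, n_rep=2))
        assert vc.sigma2_gca == vc.sigma2_sca == 0.0
        assert vc.sigma2_gca_env == vc.sigma2_sca_env == 0.0

    def test_single_env_refused(self):
        tab = pd.DataFrame({"df": [209, 20, 189, 420],
                            "ms": [3.0, 5.0, 2.0, 1.0]},
                           index=["Hybrids", "GCA", "SCA", "Error"])
        an = AnovaTable(tab, p=21, n_env=1, n_rep=2, single_env=True)
        with pytest.raises(ValueError, match="single-environment"):
            variance_components(an)


class TestGeneticRatios:
    def test_published_baker_ratios(self):
        ms = reference_mean_squares()
        for trait, expected in [("AD", 0.87), ("GY", 0.62)]:
            tab = ms[["df", trait]].rename(columns={trait: "ms"}).astype(float)
            an = AnovaTable(table=tab, p=21, n_env=2, n_rep=2)
            vc = variance_components(an, sigma2_e=reference_sigma2_e()[trait])
            assert genetic_ratios(vc, an).baker_ratio == pytest.approx(
                expected, abs=0.005)

    def test_pure_gca_gives_baker_one_and_missing_ratio(self):
        ms = reference_mean_squares()
        tab = ms[["df", "FD1"]].rename(columns={"FD1": "ms"}).astype(float)
        an = AnovaTable(table=tab, p=21, n_env=2, n_rep=2)
        vc = variance_components(an, sigma2_e=reference_sigma2_e()["FD1"])
        gr = genetic_ratios(vc, an)
        assert gr.baker_ratio == pytest.approx(1.0)
        assert gr.gca_sca_ratio is None

    def test_degenerate_baker_undefined(self):
        assert baker_ratio(0.0, 0.0) is None

    def test_heritability_within_unit_interval(self):
        ms = reference_mean_squares()
        for trait in ms.columns.drop("df"):
            tab = ms[["df", trait]].rename(columns={trait: "ms"}).astype(float)
            an = AnovaTable(table=tab, p=21, n_env=2, n_rep=2)
            vc = variance_components(an, sigma2_e=reference_sigma2_e()[trait])
            assert 0.0 <= genetic_ratios(vc, an).heritability <= 1.0


@pytest.fixture(scope="module")
def annotated():
    d = make_design(21, 2, 2)
    gen = simulate_genetics(d, 0.22, 0.27, 1.0, 0.17, 0.39, seed=81,
                            mu=5.3, var_error=1.29)
    plots = simulate_trial(d, gen, seed=82)
    wide = arithmetic_entry_means(plots).pivot_table(
        index="entry", columns="env", values="value")
    pe = pooled_error(plots)
    an = diallel_anova(wide, d, 2, float(pe["error_ms"][0]),
                       float(pe["error_df"][0]))
    res = griffing_effects(wide.mean(axis=1), d)
    return res, an, d


class TestEffectTests:
    def test_zero_effect_gives_t_zero_p_one(self, annotated):
        res, an, d = annotated
        forced = res.gca.copy()
        forced.loc[:, "estimate"] = 0.0
        res2 = type(res)(trait=res.trait, mu=res.mu, gca=forced, sca=res.sca,
                         balanced=res.balanced)
        out = effect_tests(res2, an)
        assert np.allclose(out.gca["t"], 0.0)
        assert np.allclose(out.gca["p"], 1.0)

    def test_doubling_error_scales_se_by_sqrt2(self, annotated):
        res, an, _ = annotated
        out1 = effect_tests(res, an)
        doubled = an.table.copy()
        doubled.loc[["GCAxE", "SCAxE"], "ms"] *= 2.0
        an2 = AnovaTable(doubled, an.p, an.n_env, an.n_rep)
        out2 = effect_tests(res, an2)
        assert np.allclose(out2.gca["se"], np.sqrt(2.0) * out1.gca["se"])
        assert np.allclose(out2.sca["se"], np.sqrt(2.0) * out1.sca["se"])

    def test_null_t_calibration(self):
        """Under the null, ~5% of SCA effects exceed the 5% critical value."""
        d = make_design(8, 2, 2)
        n_eff, n_sig = 0, 0
        for s in range(40):
            gen = simulate_genetics(d, 0.0, 0.0, 1.0, 0.0, 0.0,
                                    seed=5000 + s, mu=5.0, var_error=1.0)
            plots = simulate_trial(d, gen, seed=6000 + s)
            wide = arithmetic_entry_means(plots).pivot_table(
                index="entry", columns="env", values="value")
            pe = pooled_error(plots)
            an = diallel_anova(wide, d, 2, float(pe["error_ms"][0]),
                               float(pe["error_df"][0]))
            out = effect_tests(griffing_effects(wide.mean(axis=1), d), an)
            n_eff += len(out.sca)
            n_sig += int((out.sca["p"] < 0.05).sum())
        rate = n_sig / n_eff
        # effects within a diallel are correlated; allow a generous envelope
        assert abs(rate - 0.05) < 4 * np.sqrt(0.05 * 0.95 / n_eff) + 0.02
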