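import numpy as np
import pandas as pd
import pytest

from diallelkit import make_design, simulate_genetics, simulate_trial
from diallelkit.mixedmodel import RandomTerm, fit_mixed, indicator, reml_loglik
from diallelkit.trial_means import (arithmetic_entry_means, entry_means,
                                    pooled_error, screen_outliers)


@pytest.fixture(scope="module")
def balanced_plots():
    d = make_design(6, n_env=2, n_rep=2, block_size=5)
    gen = simulate_genetics(d, 0.4, 0.2, 1.0, 0.1, 0.1, seed=31, mu=10.0,
                            var_block=0.3, var_error=0.8)
    return d, simulate_trial(d, gen, seed=32)


class TestOutlierScreening:
    def test_planted_outlier_flagged(self, balanced_plots):
        _, plots = balanced_plots
        spiked = plots.copy()
        spiked.loc[7, "GY"] += 50.0
        flagged = screen_outliers(spiked, threshold_sd=3.5)
        assert 7 in set(flagged["row"])
        # input not mutated
        assert plots.loc[7, "GY"] == balanced_plots[1].loc[7, "GY"]

    def test_infinite_threshold_flags_nothing(self, balanced_plots):
        _, plots = balanced_plots
        assert screen_outliers(plots, threshold_sd=np.inf).empty

    def test_clean_data_rarely_flagged_at_threshold_4(self):
        d = make_design(21, n_env=2, n_rep=2)
        n_flagged = 0
        for s in range(5):
            gen = simulate_genetics(d, 0.22, 0.27, 1.0, 0.17, 0.39,
                                    seed=100 + s, mu=5.3, var_error=1.29)
            plots = simulate_trial(d, gen, seed=200 + s)
            n_flagged += len(screen_outliers(plots, threshold_sd=4.0))
        assert n_flagged <= 2  # ~5% chance of any flag per 840-plot trial

    def test_single_replicate_refused(self, balanced_plots):
        _, plots = balanced_plots
        solo = plots[plots["rep"] == 1]
        with pytest.raises(ValueError, match="fewer than 2 replicates"):
            screen_outliers(solo)


class TestEntryMeans:
    def test_blue_equals_arithmetic_mean_without_block_variance(self):
        d = make_design(6, n_env=1, n_rep=2, block_size=5)
        gen = simulate_genetics(d, 0.4, 0.2, seed=41, mu=10.0, var_error=0.8)
        plots = simulate_trial(d, gen, seed=42)
        blue = entry_means(
            plots, "per-env", "BLUE",
            variance_components={"rep": 0.0, "block": 0.0, "residual": 0.8},
        )
        arith = arithmetic_entry_means(plots)
        merged = blue.merge(arith, on=["entry", "env", "trait"], suffixes=("_b", "_a"))
        assert np.allclose(merged["value_b"], merged["value_a"], atol=1e-8)

    def test_blup_shrinks_toward_grand_mean(self, balanced_plots):
        _, plots = balanced_plots
        blue = entry_means(plots, "across", "BLUE")
        blup = entry_means(plots, "across", "BLUP")
        b = blue.set_index("entry")["value"]
        u = blup.set_index("entry")["value"]
        assert u.var() <= b.var()
        grand = plots["GY"].mean()
        # shrinkage entry-by-entry (balanced data)
        assert ((u - grand).abs() <= (b - grand).abs() + 1e-6).mean() > 0.9

    def test_across_env_blue_within_per_env_range(self, balanced_plots):
        _, plots = balanced_plots
        per_env = entry_means(plots, "per-env", "BLUE").pivot_table(
            index="entry", columns="env", values="value")
        across = entry_means(plots, "across", "BLUE").set_index("entry")["value"]
        lo, hi = per_env.min(axis=1), per_env.max(axis=1)
        ok = (across >= lo[across.index] - 0.05) & (across <= hi[across.index] + 0.05)
        assert ok.all()

    def test_matches_direct_gls_oracle_at_fixed_variances(self):
        """MME solution equals the brute-force dense GLS solve to 1e-8."""
        d = make_design(4, n_env=2, n_rep=2, block_size=3)
        gen = simulate_genetics(d, 0.4, 0.2, 0.5, 0.1, 0.1, seed=51, mu=8.0,
                                var_block=0.4, var_error=1.0)
        plots = simulate_trial(d, gen, seed=52)
        vc = {"env": 0.5, "rep": 0.3, "block": 0.4, "entry_env": 0.2,
              "residual": 1.0}
        blue = entry_means(plots, "across", "BLUE", variance_components=vc)

        y = plots["GY"].to_numpy()
        x, entries = indicator(plots["entry"].to_numpy())
        rep_env = (plots["env"].astype(str) + ":" + plots["rep"].astype(str)).to_numpy()
        block = np.char.add(rep_env.astype(str),
                            (":" + plots["block"].astype(str)).to_numpy().astype(str))
        ge = (plots["entry"].astype(str) + "@" + plots["env"].astype(str)).to_numpy()
        v = 1.0 * np.eye(len(y))
        for levels, s2 in [(plots["env"].to_numpy(), 0.5), (rep_env, 0.3),
                           (block, 0.4), (ge, 0.2)]:
            z, _ = indicator(levels)
            v += s2 * z @ z.T
        vi = np.linalg.inv(v)
        beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
        got = blue.set_index("entry").loc[entries, "value"].to_numpy()
        assert np.allclose(got, beta, atol=1e-8)

    def test_reml_loglik_monotone(self):
        d = make_design(5, n_env=1, n_rep=2, block_size=4)
        gen = simulate_genetics(d, 0.4, 0.2, seed=61, mu=10.0,
                                var_block=0.5, var_error=1.0)
        plots = simulate_trial(d, gen, seed=62)
        y = plots["GY"].to_numpy()
        x, _ = indicator(plots["entry"].to_numpy())
        zr, lr = indicator(plots["rep"].to_numpy())
        zb, lb = indicator((plots["rep"].astype(str) + ":" + plots["block"].astype(str)).to_numpy())
        fit = fit_mixed(y, x, [RandomTerm("rep", zr, lr), RandomTerm("block", zb, lb)],
                        track_loglik=True)
        ll = np.array(fit.loglik_history)
        assert (np.diff(ll) > -1e-6).all()

    def test_missing_entry_warned_and_absent(self, balanced_plots, caplog):
        _, plots = balanced_plots
        sub = plots.copy()
        sub.loc[sub["entry"] == "P01/P02", "GY"] = np.nan
        with caplog.at_level("WARNING"):
            res = entry_means(sub, "per-env", "BLUE")
        assert "P01/P02" not in set(res["entry"])
        assert "absent" in caplog.text


def test_pooled_error_unbiased_for_plot_error():
    d = make_design(10, n_env=2, n_rep=2, block_size=9)
    ests = []
    for s in range(20):
        gen = simulate_genetics(d, 0.3, 0.2, 0.5, 0.1, 0.1, seed=300 + s,
                                mu=5.0, var_error=1.5)
        plots = simulate_trial(d, gen, seed=400 + s)
        ests.append(pooled_error(plots)["error_ms"].iloc[0])
    assert abs(np.mean(ests) - 1.5) < 3 * np.std(ests) / np.sqrt(20)
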