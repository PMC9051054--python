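"""Forager table preparation, strategy clustering and density-NPP fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from paleoniche.foragers import (
    classify_strategy,
    compare_slopes,
    envelope_fit,
    fit_strategy_table,
    loglog_fit,
    outlier_exclusion,
    prepare_ethno,
)
from paleoniche.synthetic import EthnoSimSpec, gen_ethno_table


def table_on_line(intercept, slope, lognpp, noise=None, seed=0):
    rng = np.random.default_rng(seed)
    lognpp = np.asarray(lognpp, dtype=float)
    logd = intercept + slope * lognpp
    if noise:
        logd = logd + noise * rng.standard_normal(lognpp.size)
    return pd.DataFrame({"group": [f"g{i}" for i in range(lognpp.size)],
                         "lognpp": lognpp, "logd": logd,
                         "npp": 10.0**lognpp, "density": 10.0**logd})


class TestPrepareEthno:
    def _row(self, **kw):
        base = {"group": "g", "latitude": 45.0, "density": 1.0,
                "alt_density": np.nan, "npp": 500.0, "pct_hunt": 50.0,
                "pct_fish": 25.0, "pct_gather": 25.0,
                "trade_dependent": False, "horseback": False}
        base.update(kw)
        return base

    def test_alt_density_averaged(self):
        out = prepare_ethno(pd.DataFrame([self._row(density=1.0, alt_density=3.0)]))
        assert out.loc[0, "density"] == pytest.approx(2.0)

    def test_trade_dependent_dropped(self):
        out = prepare_ethno(pd.DataFrame([self._row(trade_dependent=True)]))
        assert len(out) == 0

    def test_latitude_boundary_inclusive_at_30(self):
        out = prepare_ethno(pd.DataFrame([self._row(latitude=29.9),
                                          self._row(latitude=30.0)]))
        assert len(out) == 1
        assert out.loc[0, "latitude"] == 30.0

    def test_nonpositive_density_rejected(self):
        out = prepare_ethno(pd.DataFrame([self._row(density=0.0),
                                          self._row(density=2.0)]))
        assert len(out) == 1

    def test_log_columns_added(self):
        out = prepare_ethno(pd.DataFrame([self._row(density=10.0, npp=1000.0)]))
        assert out.loc[0, "logd"] == pytest.approx(1.0)
        assert out.loc[0, "lognpp"] == pytest.approx(3.0)


class TestClassifyStrategy:
    def test_pure_hunting_diet_labelled_hunter(self):
        t = pd.DataFrame({"pct_hunt": [100.0, 0.0, 0.0],
                          "pct_fish": [0.0, 100.0, 0.0],
                          "pct_gather": [0.0, 0.0, 100.0]})
        labels = classify_strategy(t, seed=0)
        assert list(labels) == ["hunters", "fishers", "gatherers"]

    def test_planted_centroids_recovered(self):
        """Three well-separated centroids: >=99% label recovery."""
        hits = total = 0
        for seed in range(10):
            tab = gen_ethno_table(EthnoSimSpec(), seed=seed)
            labels = classify_strategy(tab, seed=seed)
            hits += (labels == tab["true_strategy"]).sum()
            total += len(tab)
        assert hits / total >= 0.99

    def test_deterministic_under_seed(self, ethno_table):
        a = classify_strategy(ethno_table, seed=4)
        b = classify_strategy(ethno_table, seed=4)
        assert (a == b).all()

    def test_k_exceeding_rows_rejected(self):
        t = pd.DataFrame({"pct_hunt": [50.0], "pct_fish": [25.0],
                          "pct_gather": [25.0]})
        with pytest.raises(ValueError):
            classify_strategy(t, k=3)


class TestLoglogFit:
    def test_exact_power_law(self):
        t = table_on_line(0.0, 1.0, np.linspace(1, 3, 20))
        fit = loglog_fit(t)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r == pytest.approx(1.0)

    def test_planted_slope_recovered_monte_carlo(self):
        """slope 1.85, sd 0.3, n=65: within +-0.15 for >=95% of seeds."""
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.uniform(1.4, 3.4, size=65)
            t = table_on_line(-4.0, 1.85, x, noise=0.3, seed=seed + 1000)
            hits += abs(loglog_fit(t).slope - 1.85) <= 0.15
        assert hits / n_seeds >= 0.95

    def test_unit_change_shifts_intercept_only(self):
        t = table_on_line(-2.0, 0.9, np.linspace(1.5, 3.2, 30), noise=0.2)
        fit1 = loglog_fit(t)
        t2 = t.copy()
        t2["lognpp"] = t2["lognpp"] + np.log10(2.0)  # NPP in half-units
        fit2 = loglog_fit(t2)
        assert fit2.slope == pytest.approx(fit1.slope)
        assert fit2.intercept == pytest.approx(
            fit1.intercept - fit1.slope * np.log10(2.0))

    def test_row_order_invariance(self):
        t = table_on_line(-2.0, 0.9, np.linspace(1.5, 3.2, 30), noise=0.2)
        fit1 = loglog_fit(t)
        fit2 = loglog_fit(t.sample(frac=1.0, random_state=1))
        assert fit1.slope == pytest.approx(fit2.slope)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            loglog_fit(table_on_line(0, 1, [1.0, 2.0]))
        with pytest.raises(ValueError):
            loglog_fit(table_on_line(0, 1, [2.0, 2.0, 2.0]))


class TestOutlierExclusion:
    def test_points_on_line_all_kept(self):
        t = table_on_line(0.0, 1.0, np.linspace(1, 3, 30))
        kept, excluded, _ = outlier_exclusion(t, loglog_fit(t))
        assert excluded == []
        assert len(kept) == 30

    def test_single_planted_outlier_flagged(self):
        t = table_on_line(-2.0, 1.0, np.linspace(1.5, 3.4, 50), noise=0.1,
                          seed=3)
        t.loc[25, "logd"] += 1.0  # ten residual s.d. off the line
        kept, excluded, refit = outlier_exclusion(t, loglog_fit(t))
        assert excluded == ["g25"]
        assert len(kept) == 49

    def test_refit_moves_towards_planted_truth(self):
        t = table_on_line(-2.0, 1.0, np.linspace(1.5, 3.4, 50), noise=0.1,
                          seed=4)
        t.loc[0, "logd"] += 2.0  # outlier at the low end tilts the slope
        fit0 = loglog_fit(t)
        _, _, refit = outlier_exclusion(t, fit0)
        assert abs(refit.slope - 1.0) < abs(fit0.slope - 1.0)


class TestEnvelopeFit:
    def test_collinear_points_upper_equals_lower(self):
        t = table_on_line(-1.0, 0.8, np.linspace(1.0, 3.0, 40))
        env = envelope_fit(t)
        assert env.upper.slope == pytest.approx(env.lower.slope)
        assert env.upper.intercept == pytest.approx(env.lower.intercept)
        assert env.upper.slope == pytest.approx(0.8)

    def test_uniform_band_splits_into_parallel_envelopes(self):
        """+-h band around a line: intercepts differ by ~2h, slopes equal."""
        rng = np.random.default_rng(5)
        h = 0.3
        x = rng.uniform(1.0, 3.0, size=500)
        logd = 0.5 + 1.2 * x + rng.uniform(-h, h, size=500)
        t = pd.DataFrame({"lognpp": x, "logd": logd})
        env = envelope_fit(t)
        assert env.upper.slope == pytest.approx(env.lower.slope, abs=0.1)
        assert (env.upper.intercept - env.lower.intercept
                == pytest.approx(2 * h, abs=0.12))

    def test_envelope_brackets_predictions(self, ethno_table):
        prep = prepare_ethno(ethno_table)
        prep["strategy"] = classify_strategy(prep, seed=0)
        hunters = prep[prep["strategy"] == "hunters"]
        env = envelope_fit(hunters)
        grid_x = np.linspace(hunters["lognpp"].min(), hunters["lognpp"].max(), 50)
        assert (env.upper.predict_logd(grid_x)
                >= env.lower.predict_logd(grid_x) - 1e-9).all()

    def test_too_few_bins_rejected(self):
        t = table_on_line(0.0, 1.0, [1.0, 1.05, 2.5])
        with pytest.raises(ValueError):
            envelope_fit(t)


class TestCompareSlopes:
    def test_identical_groups_give_null_result(self):
        t = table_on_line(-2.0, 1.0, np.linspace(1, 3, 40), noise=0.2, seed=6)
        out = compare_slopes(t, t.copy())
        assert out["t"] == pytest.approx(0.0, abs=1e-9)
        assert out["p_t"] == pytest.approx(1.0)

    def test_planted_slope_difference_detected(self):
        a = table_on_line(0.0, 1.0, np.linspace(1, 3, 50), noise=0.1, seed=7)
        b = table_on_line(0.0, 2.0, np.linspace(1, 3, 50), noise=0.1, seed=8)
        out = compare_slopes(a, b)
        assert out["p_t"] < 0.001

    def test_interaction_t_matches_two_regression_oracle(self):
        """Pooled-model t equals the two-fit slope contrast with pooled
        residual variance, to 1e-9."""
        a = table_on_line(-1.0, 1.1, np.linspace(1, 3, 30), noise=0.2, seed=9)
        b = table_on_line(-1.5, 0.7, np.linspace(1, 3, 25), noise=0.3, seed=10)
        out = compare_slopes(a, b)
        stats_ab = []
        for t in (a, b):
            x, y = t["lognpp"].to_numpy(), t["logd"].to_numpy()
            res = stats.linregress(x, y)
            sse = ((y - res.intercept - res.slope * x) ** 2).sum()
            sxx = ((x - x.mean()) ** 2).sum()
            stats_ab.append((res.slope, sse, sxx, len(x)))
        (b1, sse1, sxx1, n1), (b2, sse2, sxx2, n2) = stats_ab
        s2 = (sse1 + sse2) / (n1 + n2 - 4)
        t_oracle = (b2 - b1) / np.sqrt(s2 * (1 / sxx1 + 1 / sxx2))
        assert out["t"] == pytest.approx(t_oracle, abs=1e-9)


class TestStrategyTable:
    def test_planted_laws_recovered_without_noise(self, noiseless_ethno):
        spec = EthnoSimSpec()
        prep = prepare_ethno(noiseless_ethno)
        prep["strategy"] = classify_strategy(prep, seed=0)
        fits = fit_strategy_table(prep)
        for strat in ("hunters", "gatherers"):
            for kind in ("average", "lower", "upper"):
                row = fits[(fits["strategy"] == strat)
                           & (fits["kind"] == kind)].iloc[0]
                assert row["slope"] == pytest.approx(spec.slopes[strat], abs=1e-6)
                assert row["intercept"] == pytest.approx(spec.intercepts[strat],
                                                         abs=1e-6)

    def test_whole_sample_association_positive(self, ethno_table):
        prep = prepare_ethno(ethno_table)
        rho = stats.spearmanr(prep["npp"], prep["density"]).statistic
        assert rho > 0.3
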