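"""AUC / OR.10 / AICc oracles, candidate grid, selection, validation."""

import numpy as np
import pandas as pd
import pytest

from paleoniche.climate import ClimateStack
from paleoniche.evaluation import (
    aicc,
    auc,
    background_sensitivity,
    covariate_importance,
    external_validation,
    omission_rate_10,
    run_candidate_grid,
    select_model,
)
from paleoniche.grids import Layer, Mask, RasterGrid
from paleoniche.maxent import FeatureSpec, MaxEntModel, expand_features, fit_maxent, make_feature_spec
from paleoniche.occurrence import grouped_kfold


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_hand_example_three_of_four_pairs(self):
        assert auc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)

    def test_identical_multisets_give_half(self):
        assert auc([0.3, 0.7], [0.3, 0.7]) == pytest.approx(0.5)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        p, b = rng.normal(1, 1, 50), rng.normal(0, 1, 80)
        f = lambda x: np.exp(3 * x) + 1
        assert auc(p, b) == pytest.approx(auc(f(p), f(b)), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestOmissionRate:
    def test_all_above_threshold(self):
        assert omission_rate_10(np.linspace(0.1, 1, 10), [0.5, 0.9]) == 0.0

    def test_enumerated_example(self):
        train = np.arange(1, 11) * 0.1  # threshold = 0.1
        assert omission_rate_10(train, [0.05, 0.5]) == pytest.approx(0.5)

    def test_self_omission_bounded_by_percentile(self):
        rng = np.random.default_rng(1)
        train = rng.uniform(size=200)
        assert omission_rate_10(train, train) <= 0.10


class TestAicc:
    def _model(self, lam):
        spec = FeatureSpec("L", tuple(f"v{i}" for i in range(len(lam))),
                           tuple([0.0] * len(lam)), tuple([1.0] * len(lam)))
        return MaxEntModel(feature_spec=spec, lam=np.array(lam, dtype=float),
                           rm=1.0, beta=np.ones(len(lam)), log_z=0.0,
                           entropy=0.0, n_presence=0)

    def test_formula_example(self):
        """k=3, n=100, lnL=-250 -> AICc = 506.25 exactly."""
        rng = np.random.default_rng(2)
        model = self._model([0.5, -0.2, 0.1])
        fp = rng.uniform(size=(100, 3))
        fb = rng.uniform(size=(500, 3))
        # direct formula with the lnL the implementation computes
        eta = fb @ model.lam
        log_z = np.log(np.exp(eta).sum())
        lnl = float((fp @ model.lam - log_z).sum())
        k = 3
        expected = 2 * k - 2 * lnl + 2 * k * (k + 1) / (100 - k - 1)
        assert aicc(model, fp, fb) == pytest.approx(expected, rel=1e-12)
        # and the printed constant with lnL frozen at -250
        assert 2 * 3 + 500 + 24 / 96 == pytest.approx(506.25)

    def test_small_sample_guard(self):
        model = self._model([1.0, 1.0, 1.0])
        fp = np.ones((4, 3))
        with pytest.warns(UserWarning):
            assert aicc(model, fp, np.ones((10, 3))) == np.inf


class TestSelection:
    def _metrics(self):
        return pd.DataFrame([
            {"classes": "L", "rm": 1.0, "aicc": 1100.0, "or10": 0.05,
             "auc": 0.70, "delta_aicc": 100.0},
            {"classes": "LQHPT", "rm": 0.2, "aicc": 1000.0, "or10": 0.40,
             "auc": 0.90, "delta_aicc": 0.0},
            {"classes": "LQP", "rm": 0.4, "aicc": 1050.0, "or10": 0.10,
             "auc": 0.85, "delta_aicc": 50.0},
        ])

    def test_min_aicc_rule(self):
        assert select_model(self._metrics(), "min_aicc")["classes"] == "LQHPT"

    def test_compromise_prefers_low_omission_with_good_auc(self):
        """Engineered disagreement: min-AICc (LQHPT) is over-fitted (high
        OR.10); the compromise rule lands on the qualified LQP row."""
        chosen = select_model(self._metrics(), "compromise")
        assert chosen["classes"] == "LQP"

    def test_single_candidate_chosen_by_every_rule(self):
        one = self._metrics().iloc[[0]]
        for rule in ("min_aicc", "min_or10", "compromise"):
            assert select_model(one, rule)["classes"] == "L"

    def test_empty_metrics_rejected(self):
        with pytest.raises(ValueError):
            select_model(self._metrics().iloc[0:0])


@pytest.fixture(scope="module")
def niche_problem():
    """Presences concentrated at high v0: a 2-covariate toy problem."""
    rng = np.random.default_rng(3)
    bg = pd.DataFrame(rng.uniform(size=(600, 2)), columns=["v0", "v1"])
    weights = np.exp(3 * bg["v0"])
    idx = rng.choice(len(bg), size=80, p=weights / weights.sum())
    pres = bg.iloc[idx].reset_index(drop=True)
    pres["site_id"] = [f"s{i % 16}" for i in range(len(pres))]
    return pres, bg


class TestCandidateGrid:
    def test_full_grid_has_54_rows(self, niche_problem):
        pres, bg = niche_problem
        folds = grouped_kfold(pres, k=4, seed=0)
        metrics, models = run_candidate_grid(pres, bg, ["v0", "v1"], folds,
                                             knots=8, max_iter=150, tol=1e-4)
        assert len(metrics) == 54
        assert metrics[["aicc", "or10", "auc"]].notna().all().all()
        assert (metrics["delta_aicc"] >= 0).all()
        assert (metrics.loc[metrics["delta_aicc"].idxmin(), "delta_aicc"]
                == pytest.approx(0.0))

    def test_singleton_grid(self, niche_problem):
        pres, bg = niche_problem
        folds = grouped_kfold(pres, k=4, seed=0)
        metrics, models = run_candidate_grid(pres, bg, ["v0", "v1"], folds,
                                             feature_sets=("L",), rms=(1.0,))
        assert len(metrics) == 1
        assert ("L", 1.0) in models


class TestBackgroundSensitivity:
    @pytest.fixture
    def small_stack(self):
        grid = RasterGrid(30, 30, 5000.0, (0.0, 0.0))
        rng = np.random.default_rng(4)
        stack = ClimateStack(grid, {"BIO1": Layer(grid, rng.normal(size=grid.shape),
                                                  name="BIO1")})
        return stack, Mask(grid, np.ones(grid.shape, dtype=bool))

    def test_full_sample_distance_zero(self, small_stack):
        stack, mask = small_stack
        out = background_sensitivity(mask, stack, [mask.n_true], seed=0, reps=2)
        assert out["mean_max_ks"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_distance_shrinks_with_n(self, small_stack):
        stack, mask = small_stack
        out = background_sensitivity(mask, stack, [20, 200, 900], seed=1, reps=10)
        d = out["mean_max_ks"].to_numpy()
        assert d[0] > d[-1]

    def test_determinism_and_validation(self, small_stack):
        stack, mask = small_stack
        a = background_sensitivity(mask, stack, [50], seed=2, reps=3)
        b = background_sensitivity(mask, stack, [50], seed=2, reps=3)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            background_sensitivity(mask, stack, [mask.n_true + 1], seed=0)


class TestExternalValidation:
    def _setup(self, grid, suitable):
        masks = {"I1": Mask(grid, np.full(grid.shape, suitable[0])),
                 "I2": Mask(grid, np.full(grid.shape, suitable[1]))}
        cx, cy = grid.cell_centers()
        sites = pd.DataFrame([
            {"site_id": "a", "x": cx[2, 2], "y": cy[2, 2]},
            {"site_id": "b", "x": cx[5, 5], "y": cy[5, 5]},
        ])
        return masks, sites

    def test_all_suitable(self, grid):
        masks, sites = self._setup(grid, (True, True))
        frac, _ = external_validation(masks, sites)
        assert frac == 1.0

    def test_none_suitable(self, grid):
        masks, sites = self._setup(grid, (False, False))
        frac, _ = external_validation(masks, sites)
        assert frac == 0.0

    def test_half_inside(self, grid):
        vals = np.zeros(grid.shape, dtype=bool)
        vals[2, 2] = True
        masks = {"I1": Mask(grid, vals)}
        cx, cy = grid.cell_centers()
        sites = pd.DataFrame([
            {"site_id": "a", "x": cx[2, 2], "y": cy[2, 2]},
            {"site_id": "b", "x": cx[5, 5], "y": cy[5, 5]},
        ])
        frac, report = external_validation(masks, sites)
        assert frac == 0.5
        assert len(report) == 2


class TestCovariateImportance:
    def test_planted_single_driver_ranked_first(self):
        rng = np.random.default_rng(5)
        bg = pd.DataFrame(rng.uniform(size=(500, 3)), columns=["a", "b", "c"])
        w = np.exp(4 * bg["a"])
        pres = bg.iloc[rng.choice(len(bg), 60, p=w / w.sum())].reset_index(drop=True)
        spec = make_feature_spec(pd.concat([pres, bg]), "L")
        model = fit_maxent(expand_features(pres, spec),
                           expand_features(bg, spec), spec, rm=1.0)
        table = covariate_importance(model, pres, bg, seed=0, reps=5)
        assert table.iloc[0]["covariate"] == "a"
        assert table.set_index("covariate").loc["a", "contribution_pct"] > 50

    def test_single_covariate_model_owns_all_contribution(self):
        rng = np.random.default_rng(6)
        bg = pd.DataFrame({"a": rng.uniform(size=300)})
        pres = bg[bg["a"] > 0.5].sample(30, random_state=1)
        spec = make_feature_spec(pd.concat([pres, bg]), "LQ")
        model = fit_maxent(expand_features(pres, spec),
                           expand_features(bg, spec), spec, rm=1.0)
        table = covariate_importance(model, pres, bg, seed=0, reps=3)
        assert table["contribution_pct"].iloc[0] == pytest.approx(100.0)

    def test_unused_covariate_has_zero_importance(self):
        rng = np.random.default_rng(7)
        bg = pd.DataFrame(rng.uniform(size=(300, 2)), columns=["a", "b"])
        pres = bg[bg["a"] > 0.5].sample(30, random_state=2)
        spec = make_feature_spec(pd.concat([pres, bg]), "L")
        model = fit_maxent(expand_features(pres, spec),
                           expand_features(bg, spec), spec, rm=1.0)
        model.lam[1] = 0.0  # force b inactive
        table = covariate_importance(model, pres, bg, seed=0, reps=3)
        row = table.set_index("covariate").loc["b"]
        assert row["permutation_importance"] == pytest.approx(0.0, abs=1e-12)
        assert row["contribution_pct"] == pytest.approx(0.0)
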