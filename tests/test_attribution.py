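import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import GradientBoostingRegressor

from rseikit import attribution as at
from rseikit.shapley import brute_force_shapley, ensemble_shapley
from rseikit.synthetic import DriverStack, simulate
from tests.conftest import small_config, rsei_stack


def toy_samples(n=2000, seed=0, target="linear", n_cols=50):
    """Synthetic sample table with pixel coordinates and 1 km blocks."""
    rng = np.random.default_rng(seed)
    rows = np.arange(n) // n_cols
    cols = np.arange(n) % n_cols
    x = (cols + 0.5) * 500.0
    y = (rows + 0.5) * 500.0
    data = {
        "x": x,
        "y": y,
        "year": 2000,
        "block_id": at.block_ids(x, y),
        "section": "north",
    }
    for name in at.FEATURE_NAMES:
        data[name] = rng.random(n)
    df = pd.DataFrame(data)
    if target == "linear":
        df["rsei"] = (
            0.3 * df.precipitation + 0.25 * df.temperature + 0.2 * df.dem
            + 0.15 * df.slope + 0.1 * df.gdp
        )
    elif target == "noise":
        df["rsei"] = rng.random(n)
    elif target == "interaction":
        df["rsei"] = df.precipitation * df.nighttime_light + 0.05 * rng.random(n)
    elif target == "constant":
        df["rsei"] = 0.5
    return df


class TestBuildSamples:
    def test_nearest_epoch_mapping(self):
        stack = DriverStack(grid=None, layers={}, epoch_years=(2000, 2005, 2010, 2015, 2020))
        assert stack.nearest_epoch(2003) == 2005
        assert stack.nearest_epoch(2002) == 2000
        assert stack.nearest_epoch(2013) == 2015

    def test_records_and_blocks(self, small_run, small_samples):
        cfg, corridor, drivers, scenes, truth = small_run
        n_pixels = int(corridor.buffer_mask.sum())
        assert len(small_samples) == n_pixels * len(cfg.years)
        # 1 km blocks on a 500 m grid: 2x2 pixels share a block
        bx = np.floor(small_samples["x"] / 1000.0)
        by = np.floor(small_samples["y"] / 1000.0)
        np.testing.assert_array_equal(
            small_samples["block_id"], bx.astype(np.int64) * 1_000_003 + by.astype(np.int64)
        )

    def test_feature_values_track_epoch(self):
        cfg = small_config(seed=2, years=(2002, 2003), epoch_drift_sd=0.5)
        corridor, drivers, scenes, truth = simulate(cfg)
        results = rsei_stack(scenes, corridor.buffer_mask)
        samples = at.build_samples({r.year: r.rsei_layer for r in results}, drivers, corridor)
        for year, epoch in ((2002, 2000), (2003, 2005)):
            sub = samples[samples["year"] == year]
            r = np.rint(sub["y"].to_numpy() / 500.0 - 0.5).astype(int)
            c = np.rint(sub["x"].to_numpy() / 500.0 - 0.5).astype(int)
            np.testing.assert_array_equal(
                sub["temperature"].to_numpy(), drivers.layers[epoch]["temperature"][r, c]
            )

    def test_empty_epochs_error(self, small_run, small_rsei):
        _, corridor, drivers, *_ = small_run
        rsei_by_year, _ = small_rsei
        empty = DriverStack(grid=drivers.grid, layers={}, epoch_years=())
        with pytest.raises(ValueError):
            at.build_samples(rsei_by_year, empty, corridor)


class TestSpatialBlockSplit:
    def test_no_overlap_and_count(self):
        df = toy_samples(n=400)  # 100 blocks of 2x2 pixels
        assert df["block_id"].nunique() == 100
        plan = at.spatial_block_split(df, test_fraction=0.2, seed=77)
        assert len(plan.test_blocks) == 20
        assert set(plan.train_blocks).isdisjoint(plan.test_blocks)

    def test_deterministic(self):
        df = toy_samples(n=400)
        a = at.spatial_block_split(df, seed=77)
        b = at.spatial_block_split(df, seed=77)
        np.testing.assert_array_equal(a.test_blocks, b.test_blocks)

    def test_records_follow_blocks(self):
        df = toy_samples(n=400)
        plan = at.spatial_block_split(df, seed=1)
        assert plan.train_mask(df).sum() + plan.test_mask(df).sum() == len(df)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            at.SplitPlan(
                train_blocks=np.array([1, 2]), test_blocks=np.array([2, 3]),
                test_fraction=0.5, seed=0,
            )


class TestTuneAndFit:
    def test_linear_target_learned(self):
        # noiseless linear target on 5 informative features; features are
        # quantised to a coarse lattice so the function is exactly
        # tree-representable and the 0.99 bar measures learning, not the
        # piecewise-constant interpolation bias of tree ensembles
        df = toy_samples(n=4000, target="linear")
        informative = ("precipitation", "temperature", "dem", "slope", "gdp")
        for f in informative:
            df[f] = np.round(df[f] * 3) / 3
        df["rsei"] = (
            0.3 * df.precipitation + 0.25 * df.temperature + 0.2 * df.dem
            + 0.15 * df.slope + 0.1 * df.gdp
        )
        plan = at.spatial_block_split(df, seed=77)
        model, report = at.fit_and_evaluate(
            df, plan, grid={"max_depth": [7], "learning_rate": [0.3], "subsample": [1.0]},
            max_rounds=600, early_stopping=80, seed=77,
        )
        assert report.test_r2 >= 0.99

    def test_noise_target_not_learned(self):
        df = toy_samples(n=2000, target="noise")
        plan = at.spatial_block_split(df, seed=77)
        model, report = at.fit_and_evaluate(df, plan, grid="reduced", seed=77)
        assert report.test_r2 <= 0.1

    def test_early_stopping_truncates(self):
        # an easy, mildly noisy target saturates well before the round cap
        df = toy_samples(n=2000, target="linear", seed=2)
        rng = np.random.default_rng(3)
        df["rsei"] += rng.normal(0.0, 0.1, len(df))
        model, report = at.tune_and_fit(df, grid="reduced", max_rounds=800, seed=1)
        assert report.rounds_used < 800

    def test_degenerate_target(self):
        df = toy_samples(n=500, target="constant")
        with pytest.raises(ValueError, match="variance"):
            at.tune_and_fit(df, grid="reduced")

    def test_cv_selects_over_grid(self):
        df = toy_samples(n=1500, target="linear")
        grid = {"max_depth": [2, 5], "learning_rate": [0.1]}
        model, report = at.tune_and_fit(
            df, grid=grid, cv_folds=3, repeats=1, max_rounds=80, seed=3
        )
        assert report.best_params["max_depth"] in (2, 5)
        assert np.isfinite(report.cv_rmse)


class TestEvaluate:
    class Fixed:
        def __init__(self, pred):
            self.pred = np.asarray(pred, dtype=float)

        def predict(self, X):
            return self.pred

    def make_test(self, targets):
        df = toy_samples(n=len(targets))
        df["rsei"] = targets
        return df

    def test_perfect(self):
        df = self.make_test([0.1, 0.5, 0.9])
        out = at.evaluate(self.Fixed([0.1, 0.5, 0.9]), df)
        assert out == {"r2": 1.0, "rmse": 0.0, "mae": 0.0}

    def test_constant_at_mean_r2_zero(self):
        df = self.make_test([0.2, 0.4, 0.6])
        out = at.evaluate(self.Fixed([0.4, 0.4, 0.4]), df)
        assert out["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed(self):
        # y = (1, 2, 4), pred = (2, 2, 3): residuals (-1, 0, 1)
        # RMSE = sqrt(2/3), MAE = 2/3, R2 = 1 - 2 / (14/3)
        df = self.make_test([1.0, 2.0, 4.0])
        out = at.evaluate(self.Fixed([2.0, 2.0, 3.0]), df)
        assert out["rmse"] == pytest.approx(np.sqrt(2.0 / 3.0))
        assert out["mae"] == pytest.approx(2.0 / 3.0)
        assert out["r2"] == pytest.approx(1.0 - 2.0 / (14.0 / 3.0))

    def test_empty_error(self):
        with pytest.raises(ValueError):
            at.evaluate(self.Fixed([]), toy_samples(n=10).iloc[:0])


class TestLeakageAudit:
    def test_planted_gap_distance(self):
        # two single-pixel clusters 4 km apart
        df = pd.DataFrame(
            {
                "x": [500.0, 4500.0],
                "y": [500.0, 500.0],
                "year": 2000,
                "block_id": [0, 4],
                "section": "north",
                "rsei": [0.4, 0.6],
                **{name: [0.1, 0.2] for name in at.FEATURE_NAMES},
            }
        )
        plan = at.SplitPlan(
            train_blocks=np.array([0]), test_blocks=np.array([4]), test_fraction=0.5, seed=0
        )
        report = at.leakage_audit(df, plan)
        assert report.d_min_km == pytest.approx(4.0)
        assert report.d_min_km <= report.d_mean_km

    def test_morans_i_chain_example(self):
        # 1-D values [1,1,2,2] on a chain: I = 1/3 under binary weights
        w = np.zeros((4, 4))
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = 1.0
        assert at.morans_i_weights(np.array([1.0, 1.0, 2.0, 2.0]), w) == pytest.approx(1 / 3)

    def test_morans_i_positive_on_smooth_field(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(0)
        field = gaussian_filter(rng.standard_normal((40, 40)), 4.0)
        rows, cols = np.mgrid[0:40, 0:40]
        coords = np.column_stack([cols.ravel() * 500.0, rows.ravel() * 500.0])
        i_value = at.morans_i(field.ravel(), coords, seed=1)
        assert 0.5 < i_value <= 1.05

    def test_constant_target_none(self):
        coords = np.random.default_rng(0).random((30, 2)) * 1e4
        with pytest.warns(UserWarning, match="Moran"):
            assert at.morans_i(np.full(30, 1.0), coords) is None


class TestShapley:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(7)
        X = rng.random((300, 4))
        y = X[:, 0] * 2.0 + X[:, 1] * X[:, 2] + 0.1 * rng.random(300)
        sk = GradientBoostingRegressor(n_estimators=25, max_depth=3, random_state=0)
        sk.fit(X, y)
        return sk, X[:40]

    def test_matches_brute_force_oracle(self, fitted):
        sk, X = fitted
        trees = [est.tree_ for est in sk.estimators_[:, 0]]
        init = float(sk.init_.constant_.ravel()[0])
        phi, base = ensemble_shapley(trees, X, 4, sk.learning_rate, init)

        def predict_expect(Xq, in_s):
            out = np.full(Xq.shape[0], init)
            for tree in trees:
                for r in range(Xq.shape[0]):
                    out[r] += sk.learning_rate * _cond(tree, 0, Xq[r], in_s)
            return out

        def _cond(t, node, x, in_s):
            if t.children_left[node] == -1:
                return t.value[node, 0, 0]
            f = t.feature[node]
            left, right = t.children_left[node], t.children_right[node]
            if in_s[f]:
                nxt = left if x[f] <= t.threshold[node] else right
                return _cond(t, nxt, x, in_s)
            wl = t.weighted_n_node_samples[left] / t.weighted_n_node_samples[node]
            return wl * _cond(t, left, x, in_s) + (1 - wl) * _cond(t, right, x, in_s)

        oracle = brute_force_shapley(predict_expect, 4, X)
        np.testing.assert_allclose(phi, oracle, atol=1e-10)

    def test_local_accuracy(self, fitted):
        sk, X = fitted
        trees = [est.tree_ for est in sk.estimators_[:, 0]]
        init = float(sk.init_.constant_.ravel()[0])
        phi, base = ensemble_shapley(trees, X, 4, sk.learning_rate, init)
        pred = sk.predict(X)
        np.testing.assert_allclose(base + phi.sum(axis=1), pred, atol=1e-8)

    def test_null_feature_zero(self, fitted):
        sk, X = fitted
        trees = [est.tree_ for est in sk.estimators_[:, 0]]
        phi, _ = ensemble_shapley(trees, X, 4, sk.learning_rate, 0.0)
        assert np.abs(phi[:, 3]).max() <= np.abs(phi[:, 0]).max() * 0.2


@pytest.fixture(scope="module")
def regime_samples():
    """South-regime synthetic samples with well-separated planted effects."""
    cfg = small_config(
        seed=17,
        grid_shape=(30, 80),
        years=tuple(range(2000, 2006)),
        index_disagreement_sd=0.02,  # keep the target close to the planted signal
        south_effects={
            "nighttime_light": -0.6, "temperature": 0.3, "precipitation": 0.25,
            "gdp": 0.2, "slope": 0.15,
        },
    )
    corridor, drivers, scenes, truth = simulate(cfg)
    results = rsei_stack(scenes, corridor.buffer_mask)
    samples = at.build_samples({r.year: r.rsei_layer for r in results}, drivers, corridor)
    return cfg, samples[samples["section"] == "south"].reset_index(drop=True)


class TestShapAnalysis:
    def test_regime_recovery_and_direction(self, regime_samples):
        cfg, south = regime_samples
        plan = at.spatial_block_split(south, seed=77)
        model, report = at.fit_and_evaluate(south, plan, grid="reduced", seed=77)
        shap = at.shap_analysis(model, south, max_records=1500, seed=0)
        assert shap.max_local_error <= 1e-6
        assert shap.top_feature() == "nighttime_light"
        dep = shap.dependence["nighttime_light"]
        assert np.corrcoef(dep["value"], dep["phi"])[0, 1] < 0

    def test_null_below_effectful(self, regime_samples):
        cfg, south = regime_samples
        model, _ = at.tune_and_fit(south, grid="reduced", seed=77)
        shap = at.shap_analysis(model, south, max_records=1500, seed=0)
        ranking = shap.global_ranking.set_index("feature")["mean_abs_phi"]
        for effectful in ("nighttime_light", "temperature", "precipitation"):
            assert ranking["aspect"] < ranking[effectful]

    def test_spatial_phi_layer(self, regime_samples):
        cfg, south = regime_samples
        model, _ = at.tune_and_fit(south, grid="reduced", seed=77)
        shap = at.shap_analysis(model, south, max_records=800, seed=0)
        layer = shap.spatial_phi_layer("nighttime_light", cfg.grid)
        assert layer.shape == cfg.grid.shape
        assert np.isfinite(layer).sum() > 0


class TestRandomVsBlock:
    def test_white_noise_near_zero(self):
        vals = []
        for seed in range(6):
            df = toy_samples(n=1200, seed=seed, target="noise")
            out = at.random_vs_block(df, seed=seed, max_rounds=80)
            vals.append(out["inflation"])
        assert max(abs(v) for v in vals) < 0.05

    def test_reproducible(self):
        df = toy_samples(n=1200, target="noise")
        a = at.random_vs_block(df, seed=5, max_rounds=60)
        b = at.random_vs_block(df, seed=5, max_rounds=60)
        assert a == b


class TestAblation:
    def test_dominant_vs_null(self, regime_samples):
        cfg, south = regime_samples
        plan = at.spatial_block_split(south, seed=77)
        dominant = at.ablation(south, "nighttime_light", plan, seed=77)
        null = at.ablation(
            south, "aspect", plan, seed=77, full_r2=dominant["r2_full"]
        )
        assert dominant["delta_r2"] > null["delta_r2"]
        assert abs(null["delta_r2"]) < 0.02

    def test_collinear_duplicate_no_loss(self):
        df = toy_samples(n=2500, target="linear")
        df["population"] = df["gdp"]  # perfectly collinear pair
        plan = at.spatial_block_split(df, seed=77)
        out = at.ablation(df, "population", plan, seed=77)
        assert abs(out["delta_r2"]) < 0.02

    def test_unknown_feature(self):
        with pytest.raises(ValueError):
            at.ablation(toy_samples(n=100), "moisture")


class TestLinearBaseline:
    def test_linear_target_parity(self):
        df = toy_samples(n=3000, target="linear")
        plan = at.spatial_block_split(df, seed=77)
        base = at.linear_baseline(df, plan)
        assert base["r2"] >= 0.999
        assert base["rmse"] == pytest.approx(0.0, abs=1e-9)

    def test_interaction_favors_boosting(self):
        df = toy_samples(n=3000, target="interaction", seed=4)
        plan = at.spatial_block_split(df, seed=77)
        base = at.linear_baseline(df, plan)
        model, report = at.fit_and_evaluate(
            df, plan, grid={"max_depth": [5], "learning_rate": [0.1]}, seed=77
        )
        assert report.test_r2 > base["r2"]
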