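"""Driver attribution of RSEI with a spatially-blocked boosted model.

Samples are pixel-year records of the RSEI target and driver features,
grouped into 1 km x 1 km spatial blocks.  Train/test splits, CV folds
and the early-stopping slice are all block-grouped so no block ever
straddles a partition.  The model is a gradient-boosted decision-tree
regression ensemble (scikit-learn backend) with subsampling, column
subsampling and early stopping; interpretation uses exact tree Shapley
values; a leakage audit reports nearest-neighbour train-test distances
and approximate Moran's I, and a record-level random split quantifies
performance inflation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import GroupShuffleSplit, train_test_split

from rseikit.shapley import ensemble_shapley
from rseikit.synthetic import DRIVER_NAMES, SECTIONS, CorridorScene, DriverStack

FEATURE_NAMES = tuple(DRIVER_NAMES)

#: Hyperparameter space explored by the full grid search.
FULL_GRID = {
    "max_depth": [3, 5, 7, 9],
    "learning_rate": [0.01, 0.05, 0.1, 0.3],
    "subsample": [0.6, 0.8, 1.0],
    "colsample": [0.6, 0.8, 1.0],
    "l1": [0, 0.5, 1],
    "l2": [1, 2, 5],
}

#: Desk-scale grid for tests and quick runs.
REDUCED_GRID = {
    "max_depth": [3],
    "learning_rate": [0.1],
    "subsample": [0.8],
    "colsample": [1.0],
    "l1": [0],
    "l2": [1],
}

DEFAULT_PARAMS = {k: v[0] for k, v in REDUCED_GRID.items()}

_L1L2_WARNED = False


@dataclass
class SplitPlan:
    train_blocks: np.ndarray
    test_blocks: np.ndarray
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_blocks) & set(self.test_blocks)
        if overlap:
            raise ValueError(f"train/test blocks overlap: {sorted(overlap)[:5]} ...")

    def train_mask(self, samples: pd.DataFrame) -> np.ndarray:
        return samples["block_id"].isin(self.train_blocks).to_numpy()

    def test_mask(self, samples: pd.DataFrame) -> np.ndarray:
        return samples["block_id"].isin(self.test_blocks).to_numpy()


@dataclass
class FitReport:
    best_params: dict
    rounds_used: int
    n_train: int
    n_test: int
    train_r2: float = np.nan
    train_rmse: float = np.nan
    train_mae: float = np.nan
    test_r2: float = np.nan
    test_rmse: float = np.nan
    test_mae: float = np.nan
    cv_rmse: float = np.nan

    def to_dict(self) -> dict:
        return {k: (v if not isinstance(v, np.generic) else v.item()) for k, v in self.__dict__.items()}


@dataclass
class LeakageReport:
    d_min_km: float
    d_mean_km: float
    moran_train: float | None
    moran_test: float | None
    inflation: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ShapReport:
    base_value: float
    phi: np.ndarray  # (n_records, n_features)
    records: pd.DataFrame  # the records phi was computed on
    global_ranking: pd.DataFrame  # feature, mean_abs_phi, rank
    dependence: dict[str, pd.DataFrame] = field(default_factory=dict)
    max_local_error: float = np.nan

    def top_feature(self) -> str:
        return str(self.global_ranking.iloc[0]["feature"])

    def spatial_phi_layer(self, feature: str, grid) -> np.ndarray:
        """Mean Shapley value per pixel across years (record coordinates)."""
        j = FEATURE_NAMES.index(feature)
        rows = np.rint(self.records["y"].to_numpy() / grid.pixel_size - 0.5).astype(int)
        cols = np.rint(self.records["x"].to_numpy() / grid.pixel_size - 0.5).astype(int)
        total = np.zeros(grid.shape)
        count = np.zeros(grid.shape)
        np.add.at(total, (rows, cols), self.phi[:, j])
        np.add.at(count, (rows, cols), 1.0)
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / count, np.nan)


class BoostedModel:
    """Gradient-boosted regression ensemble truncated at the early-stop round."""

    def __init__(self, sk_model: GradientBoostingRegressor, rounds_used: int, params: dict):
        self._model = sk_model
        self.rounds_used = int(rounds_used)
        self.params = dict(params)
        self.feature_names = list(FEATURE_NAMES)

    @property
    def learning_rate(self) -> float:
        return float(self._model.learning_rate)

    @property
    def init_value(self) -> float:
        return float(self._model.init_.constant_.ravel()[0])

    def trees(self):
        return [est.tree_ for est in self._model.estimators_[: self.rounds_used, 0]]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        pred = np.full(X.shape[0], self.init_value)
        for est in self._model.estimators_[: self.rounds_used, 0]:
            pred += self.learning_rate * est.predict(X)
        return pred


def _rsei_layers(rsei_results) -> dict[int, np.ndarray]:
    if isinstance(rsei_results, dict):
        return rsei_results
    return {res.year: res.rsei_layer for res in rsei_results}


def block_ids(x: np.ndarray, y: np.ndarray, block_m: float = 1000.0) -> np.ndarray:
    """Encode (floor(x/block), floor(y/block)) pairs as a single integer id."""
    bx = np.floor(np.asarray(x) / block_m).astype(np.int64)
    by = np.floor(np.asarray(y) / block_m).astype(np.int64)
    return bx * 1_000_003 + by


def build_samples(
    rsei_results,
    drivers: DriverStack,
    corridor: CorridorScene,
    mask: np.ndarray | None = None,
    block_m: float = 1000.0,
) -> pd.DataFrame:
    """One record per valid buffered pixel-year: target, features, block, section.

    Driver values come from the epoch year nearest each RSEI year.
    """
    layers = _rsei_layers(rsei_results)
    if not drivers.epoch_years:
        raise ValueError("driver stack has no epochs")
    if mask is None:
        mask = corridor.buffer_mask
    x, y = corridor.grid.pixel_centers()
    frames = []
    for year, layer in sorted(layers.items()):
        valid = mask & np.isfinite(layer)
        if not valid.any():
            continue
        year_drivers = drivers.for_year(year)
        data = {
            "x": x[valid],
            "y": y[valid],
            "year": year,
            "block_id": block_ids(x[valid], y[valid], block_m),
            "section": np.array(SECTIONS)[corridor.section_code[valid]],
            "rsei": layer[valid],
        }
        for name in FEATURE_NAMES:
            data[name] = np.asarray(year_drivers[name], dtype=float)[valid]
        frames.append(pd.DataFrame(data))
    if not frames:
        raise ValueError("no valid samples (empty mask or all-nodata target)")
    return pd.concat(frames, ignore_index=True)


def feature_matrix(samples: pd.DataFrame, features=FEATURE_NAMES) -> np.ndarray:
    return samples[list(features)].to_numpy(dtype=np.float64)


def spatial_block_split(samples: pd.DataFrame, test_fraction: float = 0.2, seed: int = 77) -> SplitPlan:
    """Random block-level partition (all records of a block on one side)."""
    blocks = samples["block_id"].to_numpy()
    unique_blocks = np.unique(blocks)
    if unique_blocks.size < 2:
        raise ValueError("need at least 2 spatial blocks to split")
    gss = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
    train_idx, test_idx = next(gss.split(blocks, groups=blocks))
    return SplitPlan(
        train_blocks=np.unique(blocks[train_idx]),
        test_blocks=np.unique(blocks[test_idx]),
        test_fraction=test_fraction,
        seed=seed,
    )


def _resolve_grid(grid) -> dict:
    if grid is None or grid == "reduced":
        return REDUCED_GRID
    if grid == "full":
        return FULL_GRID
    return dict(grid)


def _sk_params(params: dict, seed: int, n_estimators: int) -> dict:
    global _L1L2_WARNED
    regularized = params.get("l1", 0) != 0 or params.get("l2", 1) != 1
    if regularized and not _L1L2_WARNED:
        warnings.warn(
            "L1/L2 leaf regularization is not supported by the scikit-learn "
            "boosting backend; those grid axes are ignored",
            stacklevel=3,
        )
        _L1L2_WARNED = True
    colsample = params.get("colsample", 1.0)
    return {
        "max_depth": params.get("max_depth", 3),
        "learning_rate": params.get("learning_rate", 0.1),
        "subsample": params.get("subsample", 1.0),
        "max_features": None if colsample >= 1.0 else colsample,
        "n_estimators": n_estimators,
        "random_state": seed,
    }


def _param_combos(grid: dict) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _grouped_folds(blocks: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per record; blocks assigned to folds round-robin after a shuffle."""
    unique_blocks = rng.permutation(np.unique(blocks))
    fold_of_block = {b: i % n_folds for i, b in enumerate(unique_blocks)}
    return np.array([fold_of_block[b] for b in blocks])


def _early_stop_rounds(model: GradientBoostingRegressor, X_val, y_val, patience: int) -> int:
    best_rmse, best_k, k = np.inf, 1, 0
    for pred in model.staged_predict(X_val):
        k += 1
        rmse = float(np.sqrt(mean_squared_error(y_val, pred)))
        if rmse < best_rmse - 1e-12:
            best_rmse, best_k = rmse, k
        elif k - best_k >= patience:
            break
    return best_k


def tune_and_fit(
    train: pd.DataFrame,
    grid=None,
    cv_folds: int = 5,
    repeats: int = 3,
    early_stopping: int = 50,
    max_rounds: int = 300,
    seed: int = 77,
) -> tuple[BoostedModel, FitReport]:
    """Block-grouped grid search + final refit with early stopping.

    CV folds group whole spatial blocks; the grid search is repeated
    with ``repeats`` fold re-shuffles and scored by mean CV RMSE.  The
    winning parameters are refit on 90% of the training blocks with the
    remaining 10% (group-held-out) used to pick the stopping round.
    """
    if train.empty:
        raise ValueError("empty training set")
    y = train["rsei"].to_numpy(dtype=np.float64)
    if np.allclose(y.std(), 0.0):
        raise ValueError("degenerate target: zero variance")
    X = feature_matrix(train)
    blocks = train["block_id"].to_numpy()
    combos = _param_combos(_resolve_grid(grid))
    rng = np.random.default_rng(seed)

    best_params, best_score = combos[0], np.nan
    if len(combos) > 1:
        scores = np.zeros(len(combos))
        for rep in range(repeats):
            folds = _grouped_folds(blocks, cv_folds, rng)
            assert not any(
                set(blocks[folds == f]) & set(blocks[folds != f]) for f in range(cv_folds)
            ), "CV folds are not block-grouped"
            for ci, params in enumerate(combos):
                fold_rmse = []
                for f in range(cv_folds):
                    tr, va = folds != f, folds == f
                    model = GradientBoostingRegressor(**_sk_params(params, seed + rep, max_rounds))
                    model.fit(X[tr], y[tr])
                    pred = model.predict(X[va])
                    fold_rmse.append(np.sqrt(mean_squared_error(y[va], pred)))
                scores[ci] += np.mean(fold_rmse)
        scores /= repeats
        best_idx = int(np.argmin(scores))
        best_params, best_score = combos[best_idx], float(scores[best_idx])

    gss = GroupShuffleSplit(n_splits=1, test_size=0.1, random_state=seed + 1)
    fit_idx, val_idx = next(gss.split(X, groups=blocks))
    sk = GradientBoostingRegressor(**_sk_params(best_params, seed, max_rounds))
    sk.fit(X[fit_idx], y[fit_idx])
    rounds = _early_stop_rounds(sk, X[val_idx], y[val_idx], early_stopping)
    model = BoostedModel(sk, rounds, best_params)

    pred_train = model.predict(X)
    report = FitReport(
        best_params=best_params,
        rounds_used=rounds,
        n_train=len(train),
        n_test=0,
        train_r2=r2_score(y, pred_train),
        train_rmse=float(np.sqrt(mean_squared_error(y, pred_train))),
        train_mae=float(mean_absolute_error(y, pred_train)),
        cv_rmse=best_score,
    )
    return model, report


def evaluate(model, test: pd.DataFrame, features=FEATURE_NAMES) -> dict[str, float]:
    """R^2, RMSE, MAE on held-out records."""
    if test.empty:
        raise ValueError("empty test set")
    y = test["rsei"].to_numpy(dtype=np.float64)
    pred = model.predict(test[list(features)].to_numpy(dtype=np.float64))
    return {
        "r2": float(r2_score(y, pred)),
        "rmse": float(np.sqrt(mean_squared_error(y, pred))),
        "mae": float(mean_absolute_error(y, pred)),
    }


def fit_and_evaluate(
    samples: pd.DataFrame, plan: SplitPlan | None = None, grid=None, seed: int = 77, **tune_kwargs
) -> tuple[BoostedModel, FitReport]:
    """Convenience: split (if no plan), tune, fit, and fill test metrics."""
    if plan is None:
        plan = spatial_block_split(samples, seed=seed)
    train = samples[plan.train_mask(samples)]
    test = samples[plan.test_mask(samples)]
    model, report = tune_and_fit(train, grid=grid, seed=seed, **tune_kwargs)
    metrics = evaluate(model, test)
    report.n_test = len(test)
    report.test_r2 = metrics["r2"]
    report.test_rmse = metrics["rmse"]
    report.test_mae = metrics["mae"]
    return model, report


def morans_i_weights(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I under an explicit (dense) spatial weight matrix.

    I = n / S0 * (z' W z) / (z' z) with z the centred variable and
    S0 the sum of all weights.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    z = values - values.mean()
    denom = (z * z).sum()
    s0 = weights.sum()
    if denom == 0 or s0 == 0:
        raise ValueError("Moran's I undefined: constant variable or empty weights")
    return float(values.size / s0 * (z @ weights @ z) / denom)


def morans_i(
    values: np.ndarray,
    coords: np.ndarray,
    k: int = 8,
    cap: int = 5000,
    seed: int = 0,
) -> float | None:
    """Approximate Moran's I with k-nearest-neighbour binary weights.

    Weights are row-standardised; records beyond ``cap`` are randomly
    subsampled.  Returns None (with a warning) for a constant input.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = values.size
    if n > cap:
        idx = np.random.default_rng(seed).choice(n, cap, replace=False)
        values, coords = values[idx], coords[idx]
        n = cap
    z = values - values.mean()
    denom = (z * z).sum()
    if denom == 0:
        warnings.warn("Moran's I undefined for a constant variable", stacklevel=2)
        return None
    k = min(k, n - 1)
    tree = cKDTree(coords)
    _, neighbors = tree.query(coords, k=k + 1)
    lag = z[neighbors[:, 1:]].mean(axis=1)  # row-standardised spatial lag
    return float((z * lag).sum() / denom)


def leakage_audit(
    samples: pd.DataFrame, plan: SplitPlan, k: int = 8, cap: int = 5000, seed: int = 0
) -> LeakageReport:
    """Test-to-train nearest distances (km) and per-partition Moran's I."""
    train = samples[plan.train_mask(samples)]
    test = samples[plan.test_mask(samples)]
    if train.empty or test.empty:
        raise ValueError("both partitions must be non-empty")
    train_xy = train[["x", "y"]].drop_duplicates().to_numpy(dtype=float)
    test_xy = test[["x", "y"]].drop_duplicates().to_numpy(dtype=float)
    d, _ = cKDTree(train_xy).query(test_xy)
    return LeakageReport(
        d_min_km=float(d.min() / 1000.0),
        d_mean_km=float(d.mean() / 1000.0),
        moran_train=morans_i(train["rsei"].to_numpy(), train[["x", "y"]].to_numpy(), k, cap, seed),
        moran_test=morans_i(test["rsei"].to_numpy(), test[["x", "y"]].to_numpy(), k, cap, seed),
    )


def _fit_fixed(train: pd.DataFrame, params: dict, seed: int, max_rounds: int, early_stopping: int) -> BoostedModel:
    y = train["rsei"].to_numpy(dtype=np.float64)
    X = feature_matrix(train)
    blocks = train["block_id"].to_numpy()
    if np.unique(blocks).size >= 2:
        gss = GroupShuffleSplit(n_splits=1, test_size=0.1, random_state=seed + 1)
        fit_idx, val_idx = next(gss.split(X, groups=blocks))
    else:
        fit_idx, val_idx = train_test_split(np.arange(len(train)), test_size=0.1, random_state=seed + 1)
    sk = GradientBoostingRegressor(**_sk_params(params, seed, max_rounds))
    sk.fit(X[fit_idx], y[fit_idx])
    rounds = _early_stop_rounds(sk, X[val_idx], y[val_idx], early_stopping)
    return BoostedModel(sk, rounds, params)


def random_vs_block(
    samples: pd.DataFrame,
    params: dict | None = None,
    seed: int = 77,
    test_fraction: float = 0.2,
    max_rounds: int = 200,
    early_stopping: int = 50,
) -> dict[str, float]:
    """R^2 under a record-level random split vs the spatial block split.

    Same model parameters and seed for both; inflation is
    R^2(random) - R^2(block).
    """
    params = dict(DEFAULT_PARAMS if params is None else params)
    plan = spatial_block_split(samples, test_fraction, seed)
    train_b = samples[plan.train_mask(samples)]
    test_b = samples[plan.test_mask(samples)]
    model_b = _fit_fixed(train_b, params, seed, max_rounds, early_stopping)
    r2_block = evaluate(model_b, test_b)["r2"]

    idx_train, idx_test = train_test_split(
        np.arange(len(samples)), test_size=test_fraction, random_state=seed
    )
    model_r = _fit_fixed(samples.iloc[idx_train], params, seed, max_rounds, early_stopping)
    r2_random = evaluate(model_r, samples.iloc[idx_test])["r2"]
    return {
        "r2_block": float(r2_block),
        "r2_random": float(r2_random),
        "inflation": float(r2_random - r2_block),
    }


def shap_analysis(
    model: BoostedModel,
    samples: pd.DataFrame,
    max_records: int = 2000,
    seed: int = 0,
) -> ShapReport:
    """Exact Shapley values, global ranking and dependence series."""
    records = samples
    if len(samples) > max_records:
        idx = np.random.default_rng(seed).choice(len(samples), max_records, replace=False)
        records = samples.iloc[np.sort(idx)]
    X = feature_matrix(records)
    phi, base = ensemble_shapley(
        model.trees(), X, len(FEATURE_NAMES), model.learning_rate, model.init_value
    )
    pred = model.predict(X)
    max_err = float(np.abs(base + phi.sum(axis=1) - pred).max())
    mean_abs = np.abs(phi).mean(axis=0)
    ranking = (
        pd.DataFrame({"feature": FEATURE_NAMES, "mean_abs_phi": mean_abs})
        .sort_values("mean_abs_phi", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    dependence = {
        name: pd.DataFrame({"value": X[:, j], "phi": phi[:, j]})
        for j, name in enumerate(FEATURE_NAMES)
    }
    return ShapReport(
        base_value=base,
        phi=phi,
        records=records.reset_index(drop=True),
        global_ranking=ranking,
        dependence=dependence,
        max_local_error=max_err,
    )


def ablation(
    samples: pd.DataFrame,
    feature_name: str,
    plan: SplitPlan | None = None,
    params: dict | None = None,
    seed: int = 77,
    max_rounds: int = 200,
    early_stopping: int = 50,
    full_r2: float | None = None,
) -> dict[str, float]:
    """R^2 drop from removing one feature, same split and seed.

    Pass ``full_r2`` to reuse a previously computed full-model score.
    """
    if feature_name not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature_name!r}")
    params = dict(DEFAULT_PARAMS if params is None else params)
    if plan is None:
        plan = spatial_block_split(samples, seed=seed)
    train = samples[plan.train_mask(samples)]
    test = samples[plan.test_mask(samples)]
    if full_r2 is None:
        model_full = _fit_fixed(train, params, seed, max_rounds, early_stopping)
        full_r2 = evaluate(model_full, test)["r2"]

    reduced = [f for f in FEATURE_NAMES if f != feature_name]
    train_red = train.drop(columns=feature_name)
    y = train_red["rsei"].to_numpy(dtype=np.float64)
    X = train_red[reduced].to_numpy(dtype=np.float64)
    blocks = train_red["block_id"].to_numpy()
    gss = GroupShuffleSplit(n_splits=1, test_size=0.1, random_state=seed + 1)
    fit_idx, val_idx = next(gss.split(X, groups=blocks))
    sk = GradientBoostingRegressor(**_sk_params(params, seed, max_rounds))
    sk.fit(X[fit_idx], y[fit_idx])
    rounds = _early_stop_rounds(sk, X[val_idx], y[val_idx], early_stopping)
    model_abl = BoostedModel(sk, rounds, params)
    ablated_r2 = evaluate(model_abl, test, features=reduced)["r2"]
    return {
        "feature": feature_name,
        "r2_full": float(full_r2),
        "r2_ablated": float(ablated_r2),
        "delta_r2": float(full_r2 - ablated_r2),
    }


def linear_baseline(samples: pd.DataFrame, plan: SplitPlan) -> dict[str, float]:
    """Ordinary least squares on the same features and split."""
    train = samples[plan.train_mask(samples)]
    test = samples[plan.test_mask(samples)]
    if train.empty or test.empty:
        raise ValueError("both partitions must be non-empty")
    lin = LinearRegression()
    lin.fit(feature_matrix(train), train["rsei"].to_numpy(dtype=np.float64))
    y = test["rsei"].to_numpy(dtype=np.float64)
    pred = lin.predict(feature_matrix(test))
    return {
        "r2": float(r2_score(y, pred)),
        "rmse": float(np.sqrt(mean_squared_error(y, pred))),
        "mae": float(mean_absolute_error(y, pred)),
    }
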