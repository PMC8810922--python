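"""Model-zoo contracts: splitting, forests, iterative selection, Boruta,
baselines, and the nearest-neighbor null."""

import math

import numpy as np
import pandas as pd
import pytest

import depcompress as dc
from depcompress.models import (ModelConfig, boruta_confirm, build_target_models,
                                fit_baselines, fit_rf, fit_reduced_and_top10,
                                fit_univariate, iterative_feature_selection,
                                nearest_neighbor_predict, split_cells)
from depcompress.preprocess import FeatureDescriptor, FeatureTable


def _table(X: np.ndarray, prefix: str = "F") -> FeatureTable:
    descs = [FeatureDescriptor("CERES", f"{prefix}{j}") for j in range(X.shape[1])]
    return FeatureTable(pd.DataFrame(X, columns=[d.key for d in descs]), descs, "T")


def test_split_cells_contract():
    cells = [f"c{i:03d}" for i in range(100)]
    cfg = ModelConfig(seed=4)
    split = split_cells(cells, cfg)
    assert len(split.train_cells) == 85 and len(split.test_cells) == 15
    assert set(split.train_cells) | set(split.test_cells) == set(cells)
    assert not set(split.train_cells) & set(split.test_cells)
    again = split_cells(cells, cfg)
    assert again.train_cells == split.train_cells
    with pytest.raises(ValueError):
        split_cells(["only"], cfg)


def test_fit_rf_echoes_reference_hyperparameters():
    rng = np.random.default_rng(0)
    table = _table(rng.standard_normal((40, 20)))
    y = rng.standard_normal(40)
    cfg = ModelConfig(seed=1)
    model = fit_rf(table, y, cfg)
    est = model.estimator
    assert est.n_estimators == 1000 and est.max_depth == 15
    assert est.min_samples_leaf == 5
    assert est.max_features == math.ceil(math.log2(20))


def test_constant_single_feature_predicts_training_mean():
    table = _table(np.ones((30, 1)))
    y = np.arange(30, dtype=float)
    model = fit_rf(table, y, ModelConfig(n_trees=400, seed=0))
    pred = model.predict(table)
    assert np.ptp(pred) == 0  # nothing to split on: constant output
    # each tree averages a bootstrap resample, so the ensemble mean sits
    # near (not exactly at) the training mean
    assert abs(pred[0] - y.mean()) < 1.0


def test_fixed_seed_gives_identical_importances():
    rng = np.random.default_rng(3)
    table = _table(rng.standard_normal((50, 8)))
    y = rng.standard_normal(50)
    cfg = ModelConfig(n_trees=50, seed=9)
    a = fit_rf(table, y, cfg)
    b = fit_rf(table, y, cfg)
    assert all(a.importances[d] == b.importances[d] for d in a.features)


def test_iterative_selection_quartile_arithmetic():
    """6400 features shrink to 1600 -> 400 -> 100 over three rounds."""
    rng = np.random.default_rng(1)
    table = _table(rng.standard_normal((30, 6400)))
    y = rng.standard_normal(30)
    cfg = ModelConfig(n_trees=15, seed=2)
    survivors = iterative_feature_selection(table, y, cfg)
    assert len(survivors) == 100
    # two features: ceil(0.5) = 1 after round one, stable thereafter
    t2 = _table(rng.standard_normal((30, 2)))
    assert len(iterative_feature_selection(t2, y, cfg)) == 1


def test_iterative_selection_keeps_strong_planted_predictor():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((60, 64))
    y = 1.2 * X[:, 5] + 0.3 * rng.standard_normal(60)
    survivors = iterative_feature_selection(_table(X), y,
                                            ModelConfig(n_trees=60, seed=0))
    assert FeatureDescriptor("CERES", "F5") in survivors


def test_boruta_confirms_exact_copy_of_target():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 10))
    y = X[:, 0].copy()
    conf = boruta_confirm(_table(X), y, ModelConfig(n_trees=60,
                                                    boruta_max_iter=25, seed=1))
    assert FeatureDescriptor("CERES", "F0") in conf


def test_reduced_and_top10_nesting():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((60, 15))
    y = X[:, :3].sum(axis=1) + 0.2 * rng.standard_normal(60)
    table = _table(X)
    cfg = ModelConfig(n_trees=60, top_k=10, seed=0)
    confirmed = [FeatureDescriptor("CERES", f"F{j}") for j in range(7)]
    reduced, top10 = fit_reduced_and_top10(table, y, cfg, confirmed)
    assert set(top10.features) <= set(reduced.features)
    assert len(top10.features) == 7  # fewer confirmed than top_k -> use all
    with pytest.raises(ValueError):
        fit_reduced_and_top10(table, y, cfg, [])


def test_univariate_perfect_and_matching_fit_rf():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(80)
    y = x.copy()
    table = _table(x[:, None])
    cfg = ModelConfig(n_trees=80, seed=3)
    uni = fit_univariate(table, y, cfg)
    train, test = slice(0, 60), slice(60, 80)
    uni_train = fit_univariate(_table(x[:60, None]), y[:60], cfg)
    pred = uni_train.estimator.predict(x[60:, None])
    assert dc.r_squared(y[60:], pred) >= 0.95
    same = fit_rf(table, y, cfg)
    assert np.allclose(uni.predict(table), same.predict(table))


def test_baselines_contract():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((50, 8))
    beta = np.array([1.0, -2.0, 0.5, 0, 0, 0, 0, 0])
    y = X @ beta
    cfg = ModelConfig(n_trees=30, seed=0)
    models = {m.variant: m for m in fit_baselines(_table(X), y, cfg)}
    lin_pred = models["linear_baseline"].estimator.predict(X)
    assert dc.r_squared(y, lin_pred) > 1 - 1e-9
    assert models["elasticnet_baseline"].estimator.alpha == 0.1
    assert len(models["rf_quartile_baseline"].features) == math.ceil(8 / 4)


def test_nearest_neighbor_null_rules():
    emb = pd.DataFrame({"umap_1": [0.0, 1.0, 0.1, 0.5],
                        "umap_2": [0.0, 0.0, 0.0, 0.0]},
                       index=["A", "B", "T1", "T2"])
    ceres = pd.DataFrame({"g1": [5.0, 9.0], "g2": [-1.0, 2.0]}, index=["A", "B"])
    pred = nearest_neighbor_predict(emb, ceres, ["T1", "T2"])
    assert (pred.loc["T1"] == ceres.loc["A"]).all()   # 0.1 < 0.9
    assert (pred.loc["T2"] == ceres.loc["A"]).all()   # tie -> smallest ID
    coincident = nearest_neighbor_predict(emb, ceres, ["T1"])
    assert (coincident.loc["T1"] == ceres.loc["A"]).all()
    with pytest.raises(KeyError):
        nearest_neighbor_predict(emb, ceres, ["missing"])


def test_pipeline_feature_sets_are_nested(small_dataset):
    """top10 <= confirmed <= iterative survivors <= assembled features."""
    ds, truth = small_dataset
    target = truth.genes_of_class("selective")[0]
    cfg = ModelConfig(n_trees=50, boruta_max_iter=20, seed=2)
    bundle = build_target_models(ds, target, cfg, fit_univariates=False)
    assembled = set(bundle.table.descriptors)
    assert set(bundle.survivors) <= assembled
    assert set(bundle.confirmed) <= set(bundle.survivors)
    if bundle.top10 is not None:
        assert set(bundle.top10.features) <= set(bundle.confirmed)


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(retain_fraction=0)
    with pytest.raises(ValueError):
        ModelConfig(train_fraction=1.0)
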