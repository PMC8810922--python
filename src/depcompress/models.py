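"""The per-target model zoo.

For one target gene's CERES profile the pipeline is: fit a random forest on
the full design matrix, keep the top importance quartile and refit (three
rounds), confirm the survivors against shuffled shadow features (Boruta),
refit on the confirmed set (the *reduced* model), and finally refit on the
ten most important confirmed features (the *top-10* model). Univariate
forests, linear / elastic-net / single-pass-quartile baselines, and a
nearest-cell-line null complete the zoo.

Default forest hyperparameters: 1000 trees, depth 15,
min 5 samples per leaf, ceil(log2(F)) candidate features per split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression

from .preprocess import FeatureDescriptor, FeatureTable


@dataclass
class ModelConfig:
    n_trees: int = 1000
    max_depth: int = 15
    min_samples_leaf: int = 5
    max_features_rule: str = "log2_of_total"
    selection_rounds: int = 3
    retain_fraction: float = 0.25
    top_k: int = 10
    elasticnet_alpha: float = 0.1
    train_fraction: float = 0.85
    boruta_max_iter: int = 100
    boruta_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.retain_fraction <= 1):
            raise ValueError("retain_fraction must be in (0, 1]")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        for name in ("n_trees", "max_depth", "min_samples_leaf", "top_k",
                     "selection_rounds", "boruta_max_iter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SplitSpec:
    train_cells: list[str]
    test_cells: list[str]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_cells) & set(self.test_cells):
            raise ValueError("train and test cells overlap")


@dataclass
class TargetModel:
    """A fitted predictor of one gene's CERES profile."""
    target_gene: str
    variant: str
    features: list[FeatureDescriptor]
    importances: dict[FeatureDescriptor, float]
    estimator: object
    seed: int

    def predict(self, table: FeatureTable | pd.DataFrame) -> np.ndarray:
        if isinstance(table, FeatureTable):
            X = table.values[[d.key for d in self.features]].to_numpy()
        else:
            X = table[[d.key for d in self.features]].to_numpy()
        return self.estimator.predict(X)

    def top_features(self, k: int) -> list[FeatureDescriptor]:
        """The k highest-importance features; ties broken by feature order."""
        order = sorted(range(len(self.features)),
                       key=lambda i: (-self.importances[self.features[i]], i))
        return [self.features[i] for i in order[:k]]


def split_cells(cells: Sequence[str], config: ModelConfig) -> SplitSpec:
    """Uniform random train/test split, reproducible by seed."""
    cells = list(cells)
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to split")
    n_train = int(round(config.train_fraction * len(cells)))
    n_train = min(max(n_train, 1), len(cells) - 1)
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(cells))
    train = [cells[i] for i in sorted(perm[:n_train])]
    test = [cells[i] for i in sorted(perm[n_train:])]
    return SplitSpec(train, test, config.seed)


def _max_features(n: int) -> int:
    return max(1, math.ceil(math.log2(n))) if n > 1 else 1


def _forest(config: ModelConfig, n_features: int, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        max_features=_max_features(n_features),
        random_state=seed,
        n_jobs=1,
    )


def fit_rf(features: FeatureTable, target: np.ndarray | pd.Series,
           config: ModelConfig, variant: str = "full") -> TargetModel:
    """Fit the standard random forest on the given design matrix.

    Importance is mean impurity decrease; a fixed seed gives bit-identical
    importances across runs.
    """
    if len(features.descriptors) == 0:
        raise ValueError("empty feature table")
    X = features.values.to_numpy()
    y = np.asarray(target, dtype=float)
    est = _forest(config, X.shape[1], config.seed)
    est.fit(X, y)
    importances = dict(zip(features.descriptors, est.feature_importances_))
    return TargetModel(features.target_gene, variant, list(features.descriptors),
                       importances, est, config.seed)


def iterative_feature_selection(features: FeatureTable, target, config: ModelConfig
                                ) -> list[FeatureDescriptor]:
    """Three rounds of fit-and-keep-the-top-quartile.

    Each round retains ceil(retain_fraction * current) features by descending
    importance (ties broken by feature order) and refits.
    """
    current = features
    for _ in range(config.selection_rounds):
        model = fit_rf(current, target, config, variant="selection")
        n_keep = math.ceil(config.retain_fraction * len(current.descriptors))
        current = current.subset(model.top_features(n_keep))
    return list(current.descriptors)


def boruta_confirm(features: FeatureTable, target, config: ModelConfig
                   ) -> list[FeatureDescriptor]:
    """All-relevant confirmation against shuffled shadow features.

    Each iteration appends an independently permuted copy of every live
    feature, fits the forest, and marks the features whose importance beats
    the maximum shadow importance as hits. Features are confirmed or rejected
    by a two-sided binomial test (p = 0.5) on their hit counts; after the
    final iteration, still-tentative features are kept when their median
    importance exceeds the median of the max-shadow history.
    """
    y = np.asarray(target, dtype=float)
    descs = list(features.descriptors)
    if not descs:
        return []
    X = features.values.to_numpy()
    n, f = X.shape
    rng = np.random.default_rng(config.seed)
    status = np.zeros(f, dtype=int)  # 0 tentative, 1 confirmed, -1 rejected
    hits = np.zeros(f, dtype=int)
    tested = np.zeros(f, dtype=int)
    imp_hist: list[np.ndarray] = []
    shadow_max_hist: list[float] = []

    for it in range(1, config.boruta_max_iter + 1):
        live = np.flatnonzero(status >= 0)
        if len(live) == 0:
            break
        shadow_base = X[:, live]
        while shadow_base.shape[1] < 5:  # canonical minimum shadow pool
            shadow_base = np.hstack([shadow_base, X[:, live]])
        shadows = rng.permuted(shadow_base, axis=0)
        design = np.hstack([X[:, live], shadows])
        est = _forest(config, design.shape[1],
                      int(rng.integers(0, 2**31 - 1)))
        est.fit(design, y)
        imp = est.feature_importances_
        real_imp, shadow_imp = imp[:len(live)], imp[len(live):]
        shadow_max = float(shadow_imp.max())
        shadow_max_hist.append(shadow_max)
        full_imp = np.full(f, np.nan)
        full_imp[live] = real_imp
        imp_hist.append(full_imp)
        hits[live] += (real_imp > shadow_max).astype(int)
        tested[live] += 1
        if it >= 5:
            # Bonferroni over the attributes still in play, as in the
            # canonical algorithm's multiple-comparison adjustment
            thr = config.boruta_alpha / max(len(live), 1)
            for j in live:
                p = stats.binomtest(int(hits[j]), int(tested[j]), 0.5).pvalue
                if p < thr:
                    status[j] = 1 if hits[j] > tested[j] / 2 else -1
        if (status != 0).all():
            break

    # resolve tentatives against the typical best shadow, comparing only
    # iterations where the feature was live (importance scales drift as the
    # design shrinks, so a global median would be unfair)
    hist = np.vstack(imp_hist) if imp_hist else np.empty((0, f))
    shadow_arr = np.asarray(shadow_max_hist)
    for j in np.flatnonzero(status == 0):
        live_iters = np.flatnonzero(~np.isnan(hist[:, j])) if hist.size else []
        if len(live_iters) == 0:
            status[j] = -1
            continue
        med_imp = float(np.median(hist[live_iters, j]))
        med_shadow = float(np.median(shadow_arr[live_iters]))
        majority = hits[j] > tested[j] / 2  # closer to confirmed than rejected
        status[j] = 1 if (med_imp > med_shadow and majority) else -1
    return [d for j, d in enumerate(descs) if status[j] == 1]


def fit_reduced_and_top10(features: FeatureTable, target, config: ModelConfig,
                          confirmed: list[FeatureDescriptor]
                          ) -> tuple[TargetModel, TargetModel]:
    """Refit on the confirmed set, then on its <=10 most important members."""
    if not confirmed:
        raise ValueError("empty confirmed feature list: target is unpredictable")
    reduced_table = features.subset(confirmed)
    reduced = fit_rf(reduced_table, target, config, variant="reduced")
    top = reduced.top_features(config.top_k)
    top10 = fit_rf(features.subset(top), target, config, variant="top10")
    return reduced, top10


def fit_univariate(feature: FeatureTable, target, config: ModelConfig) -> TargetModel:
    """A one-feature random forest (one per candidate feature gene)."""
    if len(feature.descriptors) != 1:
        raise ValueError("fit_univariate expects exactly one feature column")
    model = fit_rf(feature, target, config, variant="univariate")
    return model


def fit_baselines(features: FeatureTable, target, config: ModelConfig
                  ) -> list[TargetModel]:
    """Linear regression, elastic net (alpha 0.1), and a single-pass
    RF-quartile model for comparison with the iterative pipeline."""
    X = features.values.to_numpy()
    y = np.asarray(target, dtype=float)
    out = []
    for variant, est in (("linear_baseline", LinearRegression()),
                         ("elasticnet_baseline",
                          ElasticNet(alpha=config.elasticnet_alpha,
                                     random_state=config.seed, max_iter=5000))):
        est.fit(X, y)
        importances = dict(zip(features.descriptors, np.abs(est.coef_).ravel()))
        out.append(TargetModel(features.target_gene, variant,
                               list(features.descriptors), importances, est,
                               config.seed))
    one_pass = replace(config, selection_rounds=1)
    survivors = iterative_feature_selection(features, y, one_pass)
    out.append(fit_rf(features.subset(survivors), y, config,
                      variant="rf_quartile_baseline"))
    return out


def nearest_neighbor_predict(embedding2d: pd.DataFrame, ceres_train: pd.DataFrame,
                             test_cells: Sequence[str]) -> pd.DataFrame:
    """Null model: copy the CERES profile of the nearest cell line.

    Distances are Euclidean in the 2-D embedding; ties resolve to the
    smallest training cell ID, and a test cell never matches itself.
    """
    test_cells = list(test_cells)
    missing = [c for c in test_cells if c not in embedding2d.index]
    if missing:
        raise KeyError(f"test cell(s) missing from embedding: {missing[:5]}")
    train_cells = sorted(ceres_train.index)  # ID order makes argmin tie-stable
    emb_train = embedding2d.loc[train_cells].to_numpy()
    emb_test = embedding2d.loc[test_cells].to_numpy()
    dist = cdist(emb_test, emb_train)
    for i, c in enumerate(test_cells):
        if c in ceres_train.index:
            dist[i, train_cells.index(c)] = np.inf
    nearest = np.argmin(dist, axis=1)
    pred = ceres_train.loc[[train_cells[j] for j in nearest]].to_numpy()
    return pd.DataFrame(pred, index=test_cells, columns=ceres_train.columns)


@dataclass
class TargetModelBundle:
    """Everything fitted for one target gene."""
    target_gene: str
    split: SplitSpec
    table: FeatureTable  # pruned + normalized, all cells
    full: TargetModel
    survivors: list[FeatureDescriptor]
    confirmed: list[FeatureDescriptor]
    reduced: TargetModel | None
    top10: TargetModel | None
    univariates: dict[FeatureDescriptor, TargetModel] = field(default_factory=dict)

    @property
    def predictable(self) -> bool:
        return self.top10 is not None


def build_target_models(dataset, target_gene: str, config: ModelConfig,
                        preprocess_config=None, fit_univariates: bool = True
                        ) -> TargetModelBundle:
    """Run the full per-target pipeline on a dataset.

    Assembles and prunes the design matrix, splits cells, z-scores with
    training-cell statistics, then runs full fit -> iterative selection ->
    Boruta -> reduced/top-10, and (optionally) univariate forests for the
    top-10 features.
    """
    from .preprocess import assemble_features, normalize, prune_features

    table = prune_features(assemble_features(dataset, target_gene), preprocess_config)
    split = split_cells(list(dataset.ceres.index), config)
    table = normalize(table, statistics_from=split.train_cells)
    y = dataset.ceres[target_gene]
    y_train = y.loc[split.train_cells].to_numpy()
    train_table = FeatureTable(table.values.loc[split.train_cells],
                               list(table.descriptors), target_gene,
                               table.normalization_state)

    full = fit_rf(train_table, y_train, config, variant="full")
    survivors = iterative_feature_selection(train_table, y_train, config)
    confirmed = boruta_confirm(train_table.subset(survivors), y_train, config)
    if confirmed:
        reduced, top10 = fit_reduced_and_top10(train_table, y_train, config, confirmed)
    else:
        reduced = top10 = None

    univariates: dict[FeatureDescriptor, TargetModel] = {}
    if fit_univariates and top10 is not None:
        for d in top10.features:
            univariates[d] = fit_univariate(train_table.subset([d]), y_train, config)

    return TargetModelBundle(target_gene, split, table, full, survivors,
                             confirmed, reduced, top10, univariates)
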