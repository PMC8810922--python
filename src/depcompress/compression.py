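"""Lossy compression of genome-scale knockout screens.

A *lossy set* is a small panel of centroid genes, derived by a resampled
k-means tight-clustering of gene CERES profiles, whose measured knockout
phenotypes predict the full genome-scale profile of a cell line. One random
forest per genome gene is trained with only the lossy panel's CERES values
as features; inference applies every model to a new cell line's panel
measurements, passing the panel genes' own measurements straight through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .models import ModelConfig, TargetModel, _forest
from .preprocess import FeatureDescriptor

SIZE_LABELS = {25: "L25", 75: "L75", 100: "L100", 200: "L200", 300: "L300"}


@dataclass
class TightClusterParams:
    """Resampling parameters for the tight-clustering procedure."""
    n_resamples: int = 10
    subsample_fraction: float = 0.7
    alpha_comembership: float = 0.8
    k_extra: int = 5  # k-means k = remaining clusters to find + k_extra
    standardize: bool = True  # cluster z-scored gene profiles (shape, not magnitude)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")


@dataclass
class LossySet:
    size_label: str
    genes: list[str]  # ordered centroids
    cluster_members: dict[str, list[str]]
    tightness: dict[str, float]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("centroid genes must be distinct")
        for c in self.genes:
            if c not in self.cluster_members.get(c, []):
                raise ValueError(f"centroid {c} missing from its own member list")


@dataclass
class CompressionModelStore:
    lossy_set: LossySet
    models: dict[str, TargetModel]
    release_tag: str = "synthetic"


def _comembership(X: np.ndarray, k: int, params: TightClusterParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Fraction of resampled k-means runs in which each gene pair co-clusters.

    Each resample subsamples cells (columns) and clusters the gene profiles.
    """
    n = X.shape[0]
    counts = np.zeros((n, n))
    n_cols = max(2, int(round(params.subsample_fraction * X.shape[1])))
    for _ in range(params.n_resamples):
        cols = rng.choice(X.shape[1], size=n_cols, replace=False)
        km = KMeans(n_clusters=k, n_init=1,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        labels = km.fit_predict(X[:, cols])
        same = labels[:, None] == labels[None, :]
        counts += same
    return counts / params.n_resamples


def _best_tight_cluster(C: np.ndarray, alpha: float) -> list[int] | None:
    """Largest (then tightest) index set with pairwise co-membership >= alpha."""
    n = C.shape[0]
    best: list[int] | None = None
    best_key = (-1, -1.0)
    for i in range(n):
        order = np.argsort(-C[i])
        cand = [i]
        for j in order:
            if j == i or C[i, j] < alpha:
                continue
            if all(C[j, m] >= alpha for m in cand):
                cand.append(int(j))
        if len(cand) < 2:
            continue
        sub = C[np.ix_(cand, cand)]
        tight = float((sub.sum() - len(cand)) / (len(cand) * (len(cand) - 1)))
        key = (len(cand), tight)
        if key > best_key:
            best_key, best = key, cand
    return best


def tight_clusters(ceres_train: pd.DataFrame, target_k: int,
                   params: TightClusterParams | None = None,
                   allow_singletons: bool = True) -> LossySet:
    """Derive a lossy set of ``target_k`` centroid genes by tight clustering.

    ``ceres_train`` is cell x gene; genes are clustered on their raw CERES
    profiles. Repeatedly: subsample cells, run k-means over gene profiles,
    accumulate gene-gene co-membership fractions; extract the largest maximal
    gene set with pairwise co-membership >= alpha, remove it, and re-run
    until ``target_k`` clusters exist. The centroid of a cluster is the
    member with the highest mean co-membership to it (ties: smallest distance
    to the cluster's mean profile, then symbol order).

    When no multi-gene tight cluster remains, ``allow_singletons`` fills the
    panel with singleton clusters picked by descending profile variance
    (otherwise an error reports the achieved count).
    """
    params = params or TightClusterParams()
    genes = list(ceres_train.columns)
    if target_k >= len(genes):
        raise ValueError("target_k must be smaller than the gene count")
    X_all = ceres_train.to_numpy().T  # genes x cells
    var = X_all.var(axis=1)
    gene_var = dict(zip(genes, var))
    if params.standardize:
        # near-constant (common-essential / nonessential) genes would otherwise
        # form large stable blobs that crowd out the informative pathway
        # clusters; clustering profile *shape* keeps the panel informative
        sd = X_all.std(axis=1, ddof=1)
        X_all = (X_all - X_all.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    rng = np.random.default_rng(params.seed)

    remaining = list(genes)
    clusters: list[tuple[str, list[str], float]] = []  # centroid, members, tightness
    while len(clusters) < target_k:
        if not remaining:
            raise ValueError(
                f"could not reach {target_k} tight clusters: achieved "
                f"{len(clusters)}; consider lowering alpha_comembership")
        idx = [genes.index(g) for g in remaining]
        X = X_all[idx]
        k = min((target_k - len(clusters)) + params.k_extra, len(remaining))
        C = _comembership(X, max(k, 1), params, rng)
        members_idx = _best_tight_cluster(C, params.alpha_comembership)
        if members_idx is None:
            if not allow_singletons:
                raise ValueError(
                    f"could not reach {target_k} tight clusters: achieved "
                    f"{len(clusters)}; consider lowering alpha_comembership")
            # fill with the most variable (most informative) remaining genes
            fill = sorted(remaining, key=lambda g: (-gene_var[g], g))
            for g in fill[:target_k - len(clusters)]:
                clusters.append((g, [g], 1.0))
            break
        members = [remaining[j] for j in members_idx]
        sub = C[np.ix_(members_idx, members_idx)]
        mean_co = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        tight = float(mean_co.mean())
        mean_profile = X[members_idx].mean(axis=0)
        dist = {g: float(np.linalg.norm(X[members_idx[i]] - mean_profile))
                for i, g in enumerate(members)}
        centroid = sorted(members,
                          key=lambda g: (-mean_co[members.index(g)], dist[g], g))[0]
        clusters.append((centroid, sorted(members), tight))
        remaining = [g for g in remaining if g not in set(members)]

    return LossySet(
        size_label=SIZE_LABELS.get(target_k, "custom"),
        genes=[c for c, _, _ in clusters],
        cluster_members={c: m for c, m, _ in clusters},
        tightness={c: t for c, _, t in clusters},
    )


def fit_compression_models(ceres_train: pd.DataFrame, lossy_set: LossySet,
                           config: ModelConfig | None = None,
                           target_genes: list[str] | None = None
                           ) -> CompressionModelStore:
    """One forest per gene, with only the lossy panel's CERES as features.

    A panel gene's own model excludes itself from its features.
    ``target_genes`` restricts the store to a subset (panel genes always pass
    through at inference regardless).
    """
    config = config or ModelConfig()
    if not lossy_set.genes:
        raise ValueError("empty lossy set")
    missing = [g for g in lossy_set.genes if g not in ceres_train.columns]
    if missing:
        raise KeyError(f"lossy gene(s) absent from training matrix: {missing[:5]}")
    targets = list(target_genes) if target_genes is not None else list(ceres_train.columns)
    lossy = list(lossy_set.genes)
    X_lossy = ceres_train[lossy].to_numpy()
    col_of = {g: j for j, g in enumerate(lossy)}
    models: dict[str, TargetModel] = {}
    for gene in targets:
        feats = [g for g in lossy if g != gene]
        if gene in col_of:
            cols = [j for j in range(len(lossy)) if j != col_of[gene]]
            X = X_lossy[:, cols]
        else:
            X = X_lossy
        y = ceres_train[gene].to_numpy()
        est = _forest(config, X.shape[1], config.seed)
        est.fit(X, y)
        descs = [FeatureDescriptor("CERES", g) for g in feats]
        models[gene] = TargetModel(gene, "compression", descs,
                                   dict(zip(descs, est.feature_importances_)),
                                   est, config.seed)
    return CompressionModelStore(lossy_set, models)


def extract_lossy(full_profile: pd.Series, lossy_set: LossySet) -> pd.Series:
    """Sub-vector of a genome profile at the panel genes, in panel order."""
    for g in lossy_set.genes:
        if g not in full_profile.index:
            raise KeyError(f"profile is missing lossy gene {g!r}")
    return full_profile.loc[lossy_set.genes]


def infer_genome(store: CompressionModelStore,
                 lossy_measurements: pd.DataFrame) -> pd.DataFrame:
    """Predict the full CERES matrix from panel measurements.

    ``lossy_measurements`` is cell x panel-gene. Panel genes' own predictions
    are their measured values (exact pass-through).
    """
    lossy = store.lossy_set.genes
    missing = [g for g in lossy if g not in lossy_measurements.columns]
    if missing:
        raise KeyError(f"missing lossy gene column(s): {missing[:5]}")
    M = lossy_measurements[lossy]
    lossy_set_ = set(lossy)
    out = {}
    for gene, model in store.models.items():
        if gene not in lossy_set_:
            out[gene] = model.estimator.predict(M.to_numpy())
    for g in lossy:  # measured values pass through exactly
        out[g] = M[g].to_numpy()
    return pd.DataFrame(out, index=lossy_measurements.index)


@dataclass
class CompressionReport:
    pearson_overall: float
    pearson_by_class: dict[str, float]
    hit_overlap: tuple[int, int] | None = None
    saturation_curve: dict[int, float] = field(default_factory=dict)


def evaluate_compression(predicted: pd.DataFrame, actual: pd.DataFrame,
                         gene_classes: dict[str, str] | None = None
                         ) -> CompressionReport:
    """Overall and per-essentiality-class Pearson r over all (cell, gene) pairs."""
    common = [g for g in predicted.columns if g in actual.columns]
    p = predicted[common].reindex(actual.index)
    a = actual[common]
    overall = float(stats.pearsonr(p.to_numpy().ravel(), a.to_numpy().ravel())[0])
    by_class: dict[str, float] = {}
    if gene_classes:
        for cls in sorted(set(gene_classes.values())):
            cols = [g for g in common if gene_classes.get(g) == cls]
            if len(cols) >= 2:
                by_class[cls] = float(stats.pearsonr(
                    p[cols].to_numpy().ravel(), a[cols].to_numpy().ravel())[0])
    return CompressionReport(overall, by_class)


def hit_overlap(predicted_profile: pd.Series, actual_profile: pd.Series,
                n_top: int = 500,
                reference_means: pd.Series | None = None) -> int:
    """Overlap of the n_top most differentially required genes.

    "Differentially required" means score minus the gene's reference mean
    (across training cell lines), ranked ascending (most negative first).
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    genes = predicted_profile.index
    if not genes.equals(actual_profile.index):
        actual_profile = actual_profile.reindex(genes)
    if n_top > len(genes):
        raise ValueError("n_top exceeds gene count")
    ref = reference_means.reindex(genes) if reference_means is not None \
        else pd.Series(0.0, index=genes)
    d_pred = (predicted_profile - ref).sort_values(kind="stable")
    d_act = (actual_profile - ref).sort_values(kind="stable")
    return len(set(d_pred.index[:n_top]) & set(d_act.index[:n_top]))


def saturation_analysis(ceres_train: pd.DataFrame, ceres_validation: pd.DataFrame,
                        sizes: list[int], params: TightClusterParams | None = None,
                        config: ModelConfig | None = None,
                        eval_genes: list[str] | None = None) -> dict[int, float]:
    """Validation-set Pearson r of compression inference per panel size.

    ``eval_genes`` restricts model fitting/evaluation to a gene subset (panel
    genes are always included via pass-through), a scale control for large
    matrices.
    """
    if len(sizes) < 2:
        raise ValueError("need at least 2 sizes")
    params = params or TightClusterParams()
    curve: dict[int, float] = {}
    for size in sizes:
        lset = tight_clusters(ceres_train, size, params)
        store = fit_compression_models(ceres_train, lset, config,
                                       target_genes=eval_genes)
        pred = infer_genome(store, ceres_validation[lset.genes])
        actual_cols = [g for g in pred.columns if g in ceres_validation.columns]
        curve[size] = evaluate_compression(pred[actual_cols],
                                           ceres_validation[actual_cols]).pearson_overall
    return curve
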