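"""Model scoring, predictability filtering, and feature-composition analyses.

Beyond held-out R², each model gets a *recall* score — the fraction of null
Spearman correlations (a random gene's actual profile against the model's
prediction) falling strictly below the model's own Spearman correlation —
and a *concordance* score, the fraction of cell lines where predicted and
actual CERES land on the same side of the -0.6 essentiality cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .preprocess import FeatureDescriptor

ESSENTIALITY_CUTOFF = -0.6

RELATION_LABELS = ("same_gene_dosage", "paralog", "lineage",
                   "mutation_synthetic_lethal", "gene_set", "functional_ceres",
                   "unclassified")


@dataclass
class EvaluationRecord:
    target_gene: str
    variant: str
    r2_cv: float = np.nan
    r2_test: float = np.nan
    recall: float = np.nan
    concordance: float = np.nan
    pearson_test: float = np.nan
    spearman_test: float = np.nan
    essentiality_cutoff: float = ESSENTIALITY_CUTOFF


@dataclass
class RelationClass:
    label: str
    evidence: str


def r_squared(actual, predicted) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot.

    Computed against the mean of ``actual``; can be negative on held-out data.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size < 2:
        raise ValueError("actual and predicted must be equal-length vectors (n >= 2)")
    ss_tot = float(((a - a.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("actual has zero variance; R^2 undefined")
    ss_res = float(((a - p) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def cross_validated_r2(model_factory, X: np.ndarray, y: np.ndarray,
                       n_splits: int = 5, seed: int = 0) -> float:
    """Mean out-of-fold R² over a k-fold split of the training cells."""
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = []
    for tr, te in kf.split(X):
        est = model_factory()
        est.fit(X[tr], y[tr])
        scores.append(r_squared(y[te], est.predict(X[te])))
    return float(np.mean(scores))


def recall_metric(predicted_target: np.ndarray, actual_matrix: pd.DataFrame,
                  target_gene: str, n_null: int = 1000, seed: int = 0) -> float:
    """Rank the model's Spearman correlation against a random-gene null.

    The model statistic is Spearman(actual target, prediction) over the
    supplied cells; each null draw replaces the actual target profile with
    the actual profile of a uniformly random non-target gene (drawn with
    replacement). Returns the fraction of null values strictly below the
    statistic.
    """
    if target_gene not in actual_matrix.columns:
        raise KeyError(f"{target_gene!r} not in actual matrix")
    if actual_matrix.shape[1] < 2:
        raise ValueError("need at least 2 genes for a null")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    pred = np.asarray(predicted_target, dtype=float)
    pred_rank = stats.rankdata(pred)
    pred_rank = (pred_rank - pred_rank.mean()) / pred_rank.std()

    ranks = stats.rankdata(actual_matrix.to_numpy(), axis=0).astype(float)
    ranks = (ranks - ranks.mean(axis=0)) / ranks.std(axis=0)
    cols = list(actual_matrix.columns)
    t_idx = cols.index(target_gene)
    n = len(pred)
    statistic = float(ranks[:, t_idx] @ pred_rank / n)

    rng = np.random.default_rng(seed)
    others = np.array([j for j in range(len(cols)) if j != t_idx])
    draws = rng.choice(others, size=n_null, replace=True)
    null = ranks[:, draws].T @ pred_rank / n
    return float(np.mean(null < statistic))


def concordance(actual, predicted, cutoff: float = ESSENTIALITY_CUTOFF) -> float:
    """Fraction of cells where both values fall on the same side of the cutoff."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("length mismatch")
    return float(np.mean((a < cutoff) == (p < cutoff)))


def filter_predictable(records: list[EvaluationRecord],
                       best_univariate_r2: dict[str, float],
                       recall_threshold: float = 0.95,
                       r2_threshold: float = 0.1) -> list[str]:
    """Targets whose top-10 model clears recall > 0.95, R² > 0.1, and has at
    least one univariate R² above zero."""
    kept = []
    for rec in records:
        if rec.variant != "top10":
            continue
        if rec.recall > recall_threshold and rec.r2_cv > r2_threshold \
                and best_univariate_r2.get(rec.target_gene, -np.inf) > 0:
            kept.append(rec.target_gene)
    return kept


def feature_source_composition(top10_features: dict[str, list[FeatureDescriptor]],
                               input_census: dict[str, int]) -> dict:
    """Pooled top-10 feature shares per source, tested against the input census.

    The chi-squared goodness-of-fit compares observed per-source counts with
    the proportions each source contributes to the assembled design matrix;
    sources with zero expected counts are collapsed out.
    """
    if not top10_features:
        raise ValueError("no models supplied")
    counts: dict[str, int] = {}
    for feats in top10_features.values():
        for d in feats:
            counts[d.source] = counts.get(d.source, 0) + 1
    total_census = sum(input_census.values())
    sources = [s for s in input_census if input_census[s] > 0]
    observed = np.array([counts.get(s, 0) for s in sources], dtype=float)
    expected = np.array([input_census[s] / total_census for s in sources]) * observed.sum()
    keep = expected > 0
    chi2, p = stats.chisquare(observed[keep], expected[keep])
    shares = {s: counts.get(s, 0) / observed.sum() for s in sources}
    return {"counts": counts, "shares": shares, "chi2": float(chi2), "chi2_p": float(p)}


def redundancy_score(top10_features: dict[str, list[FeatureDescriptor]],
                     source: str) -> float:
    """Total-to-unique feature ratio for one data source across models.

    A value of ~2 means each distinct feature of that source is reused in two
    models on average.
    """
    total, distinct = 0, set()
    for feats in top10_features.values():
        for d in feats:
            if d.source == source:
                total += 1
                distinct.add(d.name)
    if not distinct:
        return float("nan")
    return total / len(distinct)


def load_annotation_map(path, symmetric: bool = True) -> dict[str, str]:
    """Read a two-column CSV (gene, partner) into a paralog-style map.

    With ``symmetric`` both directions are entered, matching how paralog
    annotations are consumed by :func:`classify_feature_relation`.
    """
    df = pd.read_csv(path)
    a, b = df.columns[:2]
    out: dict[str, str] = {}
    for x, y in zip(df[a], df[b]):
        out[str(x)] = str(y)
        if symmetric:
            out[str(y)] = str(x)
    return out


def classify_feature_relation(feature: FeatureDescriptor, target: str,
                              paralog_map: dict[str, str] | None = None,
                              gene_sets: dict[str, set[str]] | None = None
                              ) -> RelationClass:
    """Assign one cell-type-specificity relation class to a feature-target pair.

    Precedence: same gene (dosage) > annotated paralog pair > lineage source >
    mutation source (synthetic lethal) > shared gene set > functional CERES.
    A non-CERES feature matching none of the annotations is ``unclassified``.
    """
    paralog_map = paralog_map or {}
    gene_sets = gene_sets or {}
    if feature.source != "lineage" and feature.name == target:
        return RelationClass("same_gene_dosage", feature.source)
    if paralog_map.get(feature.name) == target or paralog_map.get(target) == feature.name:
        return RelationClass("paralog", f"{feature.name}~{target}")
    if feature.source == "lineage":
        return RelationClass("lineage", feature.name)
    if feature.source.startswith("mutation"):
        return RelationClass("mutation_synthetic_lethal", feature.source)
    shared = [name for name, members in gene_sets.items()
              if feature.name in members and target in members]
    if shared:
        return RelationClass("gene_set", shared[0])
    if feature.source == "CERES":
        return RelationClass("functional_ceres", "CERES")
    return RelationClass("unclassified", feature.source)
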