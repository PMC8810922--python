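"""Desk-scale study routines: the package's headline computations.

Each function runs one self-contained experiment on planted synthetic data
and returns the quantities it measured. They are shared by the acceptance
test suite and by ``scripts/acceptance.py``; problem sizes are chosen so
each experiment completes in minutes on one CPU (documented in the methods
note).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import compression
from .evaluation import r_squared, recall_metric
from .models import (ModelConfig, boruta_confirm, build_target_models,
                     nearest_neighbor_predict)
from .preprocess import FeatureDescriptor, FeatureTable, correlation_vs_variability
from .synthetic import GeneratorConfig, generate_dataset


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 7919 + k * 104729 + 1) % (2**31 - 1)


# ---------------------------------------------------------------------------
# pipeline dominance: multivariate vs univariate vs nearest-neighbor null
# ---------------------------------------------------------------------------

def dominance_experiment(seed: int = 0, n_seeds: int = 10,
                         targets_per_seed: int = 3,
                         n_trees: int = 100, boruta_max_iter: int = 30) -> dict:
    """Held-out performance of the top-10 multivariate model against the best
    univariate model and the nearest-cell-line null, across seed-swept
    planted datasets (300 cells x 1200 genes, 40 factors)."""
    wins, margins = [], []
    model_r, nn_r = [], []
    for s in range(n_seeds):
        gcfg = GeneratorConfig(seed=_sub_seed(seed, s))
        ds, truth = generate_dataset(gcfg)
        selective = truth.genes_of_class("selective")
        rng = np.random.default_rng(_sub_seed(seed, 1000 + s))
        targets = list(rng.choice(selective, size=targets_per_seed, replace=False))
        mcfg = ModelConfig(n_trees=n_trees, boruta_max_iter=boruta_max_iter,
                           seed=_sub_seed(seed, 2000 + s))
        for gene in targets:
            bundle = build_target_models(ds, gene, mcfg)
            if bundle.top10 is None:
                wins.append(False)
                continue
            test = bundle.split.test_cells
            y = ds.ceres.loc[test, gene].to_numpy()
            Xt = bundle.table.values.loc[test]
            pred = bundle.top10.estimator.predict(
                Xt[[f.key for f in bundle.top10.features]].to_numpy())
            r2_multi = r_squared(y, pred)
            r2_uni = max(
                r_squared(y, m.estimator.predict(Xt[[m.features[0].key]].to_numpy()))
                for m in bundle.univariates.values())
            wins.append(r2_multi > r2_uni)
            margins.append(r2_multi - r2_uni)
            model_r.append(stats.pearsonr(y, pred)[0])
            nn = nearest_neighbor_predict(ds.embedding2d,
                                          ds.ceres.loc[bundle.split.train_cells], test)
            nn_r.append(stats.pearsonr(y, nn[gene].to_numpy())[0])
    return {
        "n_targets": len(wins),
        "fraction_multivariate_wins": float(np.mean(wins)),
        "mean_margin_r2": float(np.mean(margins)),
        "mean_model_pearson": float(np.mean(model_r)),
        "mean_nn_pearson": float(np.mean(nn_r)),
    }


# ---------------------------------------------------------------------------
# null calibrations
# ---------------------------------------------------------------------------

def recall_null_calibration(seed: int = 0, n_replicates: int = 200,
                            n_null: int = 200, n_cells: int = 60,
                            n_genes: int = 300) -> dict:
    """Recall of a permuted (information-free) prediction should be Uniform(0,1).

    Each replicate draws an i.i.d. Gaussian CERES matrix and scores a random
    permutation of the target's actual values.
    """
    rng = np.random.default_rng(seed)
    recalls = np.empty(n_replicates)
    for i in range(n_replicates):
        mat = pd.DataFrame(rng.standard_normal((n_cells, n_genes)),
                           columns=[f"G{j}" for j in range(n_genes)])
        target = "G0"
        pred = rng.permutation(mat[target].to_numpy())
        recalls[i] = recall_metric(pred, mat, target, n_null=n_null,
                                   seed=int(rng.integers(0, 2**31 - 1)))
    ks = stats.kstest(recalls, "uniform")
    return {"mean_recall": float(recalls.mean()), "ks_p": float(ks.pvalue),
            "recalls": recalls}


def boruta_noise_rate(seed: int = 0, n_seeds: int = 20, n_features: int = 50,
                      n_cells: int = 100, n_trees: int = 100,
                      boruta_max_iter: int = 30) -> dict:
    """Fraction of pure-noise features Boruta confirms (should be <= alpha)."""
    confirmed_counts = []
    for s in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 3000 + s))
        X = rng.standard_normal((n_cells, n_features))
        y = rng.standard_normal(n_cells)
        descs = [FeatureDescriptor("CERES", f"N{j}") for j in range(n_features)]
        table = FeatureTable(
            pd.DataFrame(X, columns=[d.key for d in descs]), descs, "target")
        cfg = ModelConfig(n_trees=n_trees, boruta_max_iter=boruta_max_iter,
                          seed=_sub_seed(seed, 4000 + s))
        confirmed_counts.append(len(boruta_confirm(table, y, cfg)))
    return {"mean_confirmed": float(np.mean(confirmed_counts)),
            "rate": float(np.mean(confirmed_counts) / n_features)}


def slope_null_calibration(seed: int = 0, n_replicates: int = 200,
                           n_genes: int = 200, n_cells: int = 100,
                           alpha: float = 0.05) -> dict:
    """Rejection rate of the correlation-vs-variability slope test on i.i.d.
    Gaussian data (no structure): should sit near alpha."""
    rng = np.random.default_rng(seed)
    rejections = 0
    pvals = np.empty(n_replicates)
    for i in range(n_replicates):
        mat = pd.DataFrame(rng.standard_normal((n_cells, n_genes)))
        res = correlation_vs_variability(mat, n_permutations=0,
                                         seed=int(rng.integers(0, 2**31 - 1)))
        pvals[i] = res["slope_p"]
        rejections += res["slope_p"] < alpha
    return {"rejection_rate": rejections / n_replicates, "p_values": pvals}


# ---------------------------------------------------------------------------
# compression recovery
# ---------------------------------------------------------------------------

def _truth_panel(truth) -> compression.LossySet:
    """One centroid per planted factor, straight from the ground truth."""
    centroids = [truth.centroid_gene[k] for k in sorted(truth.centroid_gene)]
    return compression.LossySet(
        "custom", centroids,
        {c: [c] for c in centroids}, {c: 1.0 for c in centroids})


def compression_recovery(seed: int = 0, n_trees: int = 50,
                         n_eval_genes: int = 400) -> dict:
    """Genome inference from one centroid per planted factor, plus controls.

    Measures (i) held-out overall Pearson r with the planted-centroid panel,
    (ii) the same with a random equal-size panel on architecture-free
    (all-nonessential, no planted effects) data, and (iii) what fraction of
    tight-clustering's returned centroids land in planted clusters.
    """
    gcfg = GeneratorConfig(seed=_sub_seed(seed, 11))
    ds, truth = generate_dataset(gcfg)
    rng = np.random.default_rng(_sub_seed(seed, 12))
    n_val = 45
    perm = rng.permutation(len(ds.ceres))
    val_cells = ds.ceres.index[np.sort(perm[:n_val])]
    train_cells = ds.ceres.index[np.sort(perm[n_val:])]
    train, val = ds.ceres.loc[train_cells], ds.ceres.loc[val_cells]
    mcfg = ModelConfig(n_trees=n_trees, seed=_sub_seed(seed, 13))

    panel = _truth_panel(truth)
    eval_genes = sorted(set(
        rng.choice(ds.ceres.columns, size=n_eval_genes, replace=False)
    ) | set(panel.genes))
    store = compression.fit_compression_models(train, panel, mcfg,
                                               target_genes=eval_genes)
    pred = compression.infer_genome(store, val[panel.genes])
    overall_r = compression.evaluate_compression(pred, val[pred.columns],
                                                 truth.gene_class).pearson_overall

    # negative control: random panel on data with no planted structure at all
    flat_cfg = GeneratorConfig(
        class_fractions=(0.0, 0.0, 1.0), n_factors=1, n_synthetic_lethal=0,
        n_dosage=0, n_paralog_pairs=0, n_lineage_effects=0,
        seed=_sub_seed(seed, 14))
    flat_ds, _ = generate_dataset(flat_cfg)
    rng2 = np.random.default_rng(_sub_seed(seed, 15))
    rand_genes = sorted(rng2.choice(flat_ds.ceres.columns, size=len(panel.genes),
                                    replace=False))
    rand_panel = compression.LossySet("custom", list(rand_genes),
                                      {g: [g] for g in rand_genes},
                                      {g: 1.0 for g in rand_genes})
    f_train = flat_ds.ceres.iloc[:len(train_cells)]
    f_val = flat_ds.ceres.iloc[len(train_cells):]
    f_eval = sorted(set(rng2.choice(flat_ds.ceres.columns, size=n_eval_genes,
                                    replace=False)))
    f_eval = [g for g in f_eval if g not in set(rand_genes)]
    f_store = compression.fit_compression_models(f_train, rand_panel, mcfg,
                                                 target_genes=f_eval)
    f_pred = compression.infer_genome(f_store, f_val[rand_panel.genes])
    f_pred = f_pred[f_eval]  # exclude exact pass-through from the control
    control_r = compression.evaluate_compression(
        f_pred, f_val[f_eval]).pearson_overall

    tight = compression.tight_clusters(
        train, gcfg.n_factors,
        compression.TightClusterParams(seed=_sub_seed(seed, 16)))
    in_cluster = np.mean([c in truth.cluster_assignment for c in tight.genes])
    return {"overall_r": float(overall_r), "control_r": float(control_r),
            "centroid_recovery": float(in_cluster)}


def saturation_experiment(seed: int = 0, n_seeds: int = 2,
                          n_factors: int = 20, n_genes: int = 600,
                          n_cells: int = 200, sizes: tuple = (5, 10, 20, 30),
                          n_trees: int = 40, n_eval_genes: int = 200) -> dict:
    """Validation r versus panel size: the curve should plateau at the
    planted factor count."""
    curves = []
    for s in range(n_seeds):
        gcfg = GeneratorConfig(n_cells=n_cells, n_genes=n_genes, n_factors=n_factors,
                               n_synthetic_lethal=4, n_dosage=4, n_paralog_pairs=4,
                               n_lineage_effects=4, seed=_sub_seed(seed, 21 + s))
        ds, _ = generate_dataset(gcfg)
        rng = np.random.default_rng(_sub_seed(seed, 31 + s))
        n_val = 30
        perm = rng.permutation(len(ds.ceres))
        val_cells = ds.ceres.index[np.sort(perm[:n_val])]
        train_cells = ds.ceres.index[np.sort(perm[n_val:])]
        eval_genes = sorted(rng.choice(ds.ceres.columns, size=n_eval_genes,
                                       replace=False))
        curve = compression.saturation_analysis(
            ds.ceres.loc[train_cells], ds.ceres.loc[val_cells], list(sizes),
            compression.TightClusterParams(n_resamples=6, seed=_sub_seed(seed, 41 + s)),
            ModelConfig(n_trees=n_trees, seed=_sub_seed(seed, 51 + s)),
            eval_genes=eval_genes)
        curves.append(curve)
    mean_curve = {size: float(np.mean([c[size] for c in curves])) for size in sizes}
    r_max = max(mean_curve.values())
    return {"curve": mean_curve,
            "plateau_gap_at_factor_count": float(r_max - mean_curve[n_factors])}


# ---------------------------------------------------------------------------
# exact small-instance oracles
# ---------------------------------------------------------------------------

def _set_partitions(items: list):
    """All set partitions (Bell-number enumeration) of a small list."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def louvain_vs_exhaustive(seed: int = 0) -> dict:
    """Louvain on two 5-cliques joined by one edge, against brute-force
    modularity maximization over all partitions of the 10 nodes."""
    import networkx as nx

    from .network import louvain_communities

    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    g.add_edge(0, 5)
    best_q, best_part = -np.inf, None
    for part in _set_partitions(list(g.nodes())):
        q = nx.community.modularity(g, [set(b) for b in part])
        if q > best_q:
            best_q, best_part = q, part
    comm = louvain_communities(g, seed=seed)
    blocks = {}
    for node, cid in comm.items():
        blocks.setdefault(cid, set()).add(node)
    louvain_q = nx.community.modularity(g, list(blocks.values()))
    same = {frozenset(b) for b in best_part} == {frozenset(b) for b in blocks.values()}
    return {"louvain_modularity": float(louvain_q),
            "exhaustive_modularity": float(best_q),
            "partitions_match": bool(same)}


def hit_overlap_null_expectation(seed: int = 0, n_genes: int = 100,
                                 n_top: int = 10, n_sim: int = 200) -> dict:
    """Mean hit overlap of independent random rankings vs n_top^2 / G."""
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i}" for i in range(n_genes)])
    overlaps = []
    for _ in range(n_sim):
        a = pd.Series(rng.standard_normal(n_genes), index=genes)
        b = pd.Series(rng.standard_normal(n_genes), index=genes)
        overlaps.append(compression.hit_overlap(a, b, n_top=n_top))
    return {"mean_overlap": float(np.mean(overlaps)),
            "expected": n_top ** 2 / n_genes}
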