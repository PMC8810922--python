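"""The prediction network: feature -> target edges, communities, statistics.

Aggregating the top-10 models over all targets gives a directed graph in
which an edge runs from each predictive feature (a gene, or a lineage label)
to its target gene. Community structure is extracted with Louvain; summary
statistics (mean local clustering, mean neighbor count, degree
heterogeneity) are computed on the undirected projection, and the degree
distribution is fit to a power law y = a * x^b on nodes of degree >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .models import TargetModel


@dataclass
class NetworkStats:
    clustering_coefficient: float
    mean_neighbors: float
    heterogeneity: float
    n_nodes: int
    n_edges: int


@dataclass
class PowerLawFit:
    a: float
    b: float
    r2_loglog: float


def build_network(models: list[TargetModel]) -> nx.DiGraph:
    """One directed edge per (feature, target) pair across the given models.

    Gene features use their symbol as node label; lineage features become
    ``lineage:<label>`` nodes. Parallel edges collapse, retaining the maximum
    importance.
    """
    if not models:
        raise ValueError("no models supplied")
    g = nx.DiGraph()
    for model in models:
        g.add_node(model.target_gene, kind="gene")
        for d in model.features:
            node = f"lineage:{d.name}" if d.source == "lineage" else d.name
            g.add_node(node, kind="lineage" if d.source == "lineage" else "gene")
            imp = float(model.importances.get(d, 0.0))
            if g.has_edge(node, model.target_gene):
                prev = g[node][model.target_gene]
                prev["importance"] = max(prev["importance"], imp)
            else:
                g.add_edge(node, model.target_gene, source=d.source, importance=imp)
    return g


def louvain_communities(network: nx.Graph, seed: int = 0,
                        resolution: float = 1.0) -> dict:
    """Louvain modularity-maximizing partition on the undirected projection."""
    und = network.to_undirected() if network.is_directed() else network
    if und.number_of_nodes() == 0:
        raise ValueError("empty network")
    parts = nx.community.louvain_communities(und, resolution=resolution, seed=seed)
    return {node: cid for cid, nodes in enumerate(parts) for node in nodes}


def network_stats(network: nx.Graph, undirected: bool = True) -> NetworkStats:
    """Mean clustering, mean neighbors, and degree heterogeneity.

    Heterogeneity is the coefficient of variation of the degree sequence,
    sqrt(var(k)) / mean(k) (population variance).
    """
    g = network.to_undirected() if (undirected and network.is_directed()) else network
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    mean_k = degrees.mean()
    het = float(np.sqrt(degrees.var()) / mean_k) if mean_k > 0 else 0.0
    return NetworkStats(
        clustering_coefficient=float(nx.average_clustering(g)),
        mean_neighbors=float(mean_k),
        heterogeneity=het,
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
    )


def strip_functional_edges(network: nx.DiGraph) -> nx.DiGraph:
    """Remove CERES-source edges and any node left isolated."""
    stripped = network.copy()
    drop = [(u, v) for u, v, d in stripped.edges(data=True) if d.get("source") == "CERES"]
    stripped.remove_edges_from(drop)
    stripped.remove_nodes_from(list(nx.isolates(stripped)))
    return stripped


def compare_with_without_functional(network: nx.DiGraph) -> dict:
    """Contrast the full network with the CERES-edge-stripped subnetwork.

    Returns both NetworkStats and two-sided t-tests on the per-node local
    clustering coefficients and neighbor counts. A stripped network too small
    to compare is flagged non-testable; identical distributions report p = 1.
    """
    stripped = strip_functional_edges(network)
    full_u = network.to_undirected()
    result: dict = {"with_functional": network_stats(network)}
    if stripped.number_of_nodes() < 2:
        result.update({"without_functional": None, "testable": False,
                       "clustering_t_p": np.nan, "neighbors_t_p": np.nan})
        return result
    strip_u = stripped.to_undirected()
    result["without_functional"] = network_stats(stripped)
    result["testable"] = True
    for key, values in (("clustering_t_p",
                         (list(nx.clustering(full_u).values()),
                          list(nx.clustering(strip_u).values()))),
                        ("neighbors_t_p",
                         ([d for _, d in full_u.degree()],
                          [d for _, d in strip_u.degree()]))):
        a, b = np.asarray(values[0], float), np.asarray(values[1], float)
        if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
            result[key] = 1.0
        else:
            result[key] = float(stats.ttest_ind(a, b).pvalue)
    return result


def power_law_fit(degrees) -> PowerLawFit:
    """Fit node count vs degree to y = a * x^b by log-log least squares.

    Restricted to degrees >= 2; exact (machine precision) on noiseless
    power-law counts.
    """
    degrees = np.asarray(list(degrees), dtype=float)
    degrees = degrees[degrees >= 2]
    xs, ys = np.unique(degrees, return_counts=True)
    if len(xs) < 2:
        raise ValueError("need at least 2 distinct degrees >= 2")
    lx, ly = np.log(xs), np.log(ys.astype(float))
    slope, intercept, r, _, _ = stats.linregress(lx, ly)
    return PowerLawFit(a=float(np.exp(intercept)), b=float(slope),
                       r2_loglog=float(r ** 2))


def module_regression(ceres: pd.DataFrame, module_a: list[str], module_b: list[str],
                      core_genes: list[str]) -> dict:
    """Regress a core-module score on two candidate upstream module scores.

    Per-cell module scores are the mean CERES over the module's genes. Fits
    OLS of the core score on A alone, B alone, and A+B; reports coefficients,
    their two-sided t-test p-values, AIC and BIC per model.
    """
    for name, lst in (("module_a", module_a), ("module_b", module_b),
                      ("core_genes", core_genes)):
        if not lst:
            raise ValueError(f"{name} is empty")
        missing = [g for g in lst if g not in ceres.columns]
        if missing:
            raise KeyError(f"{name} gene(s) absent: {missing[:5]}")
    if ceres.shape[0] < 4:
        raise ValueError("too few cell lines for regression")
    score_a = ceres[module_a].mean(axis=1)
    score_b = ceres[module_b].mean(axis=1)
    core = ceres[core_genes].mean(axis=1)
    out = {}
    for label, cols in (("A", {"A": score_a}), ("B", {"B": score_b}),
                        ("A+B", {"A": score_a, "B": score_b})):
        X = sm.add_constant(pd.DataFrame(cols))
        fit = sm.OLS(core, X).fit()
        out[label] = {
            "coefficients": {k: float(v) for k, v in fit.params.items() if k != "const"},
            "coefficient_p": {k: float(v) for k, v in fit.pvalues.items() if k != "const"},
            "aic": float(fit.aic),
            "bic": float(fit.bic),
        }
    return out


def edge_density_permutation(network: nx.Graph, set_a, set_b,
                             n_perm: int = 999, seed: int = 0) -> dict:
    """Depletion test for cross-edges between two node sets.

    Observed statistic: number of edges between ``set_a`` and ``set_b`` in
    the undirected projection. Null: degree-preserving double-edge-swap
    rewiring, ``n_perm`` resamples. One-sided add-one p-value for depletion,
    (1 + #{null <= observed}) / (n_perm + 1).
    """
    set_a, set_b = set(set_a), set(set_b)
    if set_a & set_b:
        raise ValueError("node sets overlap")
    g = network.to_undirected() if network.is_directed() else network.copy()

    def _cross(h: nx.Graph) -> int:
        return sum(1 for u, v in h.edges()
                   if (u in set_a and v in set_b) or (u in set_b and v in set_a))

    observed = _cross(g)
    rng = np.random.default_rng(seed)
    n_edges = g.number_of_edges()
    null = np.empty(n_perm)
    for i in range(n_perm):
        h = g.copy()
        try:
            nx.double_edge_swap(h, nswap=2 * n_edges, max_tries=40 * n_edges,
                                seed=int(rng.integers(0, 2**31 - 1)))
        except nx.NetworkXError:
            pass  # too few swappable edges; use partial rewiring
        null[i] = _cross(h)
    p = (1.0 + float(np.sum(null <= observed))) / (n_perm + 1.0)
    return {"observed": observed, "null_mean": float(null.mean()), "p_value": p}


def export_graphml(network: nx.Graph, path, communities: dict | None = None) -> None:
    g = network.copy()
    if communities:
        nx.set_node_attributes(g, communities, "community")
    nx.write_graphml(g, path)
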