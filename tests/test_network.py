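"""Prediction-network construction, communities, statistics, the power-law
fit, module regression, and the edge-density depletion test."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from depcompress.models import TargetModel
from depcompress.network import (build_network, compare_with_without_functional,
                                 edge_density_permutation, louvain_communities,
                                 module_regression, network_stats, power_law_fit,
                                 strip_functional_edges)
from depcompress.preprocess import FeatureDescriptor


def _model(target, features, source="CERES"):
    descs = [FeatureDescriptor(source, f) for f in features]
    return TargetModel(target, "top10", descs,
                       {d: 1.0 / len(descs) for d in descs}, None, 0)


def test_build_network_counts_and_attributes():
    models = [_model("T1", [f"a{i}" for i in range(10)]),
              _model("T2", [f"b{i}" for i in range(10)])]
    g = build_network(models)
    assert g.number_of_nodes() == 22 and g.number_of_edges() == 20
    assert g["a0"]["T1"]["source"] == "CERES"
    shared = [_model(t, ["hub", f"x{t}"]) for t in ("T1", "T2", "T3")]
    g2 = build_network(shared)
    assert g2.out_degree("hub") == 3


def test_lineage_features_become_labeled_nodes():
    m = _model("T1", ["skin"], source="lineage")
    g = build_network([m])
    assert "lineage:skin" in g.nodes
    assert g.nodes["lineage:skin"]["kind"] == "lineage"


def test_louvain_contracts():
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    g.add_edge(0, 5)
    comm = louvain_communities(g, seed=3)
    blocks = {}
    for n, c in comm.items():
        blocks.setdefault(c, set()).add(n)
    assert {frozenset(b) for b in blocks.values()} == \
        {frozenset(range(5)), frozenset(range(5, 10))}
    single = nx.Graph()
    single.add_node("only")
    assert louvain_communities(single) == {"only": 0}
    # partition modularity beats all-singletons
    q = nx.community.modularity(g, list(blocks.values()))
    q0 = nx.community.modularity(g, [{n} for n in g.nodes()])
    assert q >= q0


def test_network_stats_hand_examples():
    tri = network_stats(nx.complete_graph(3))
    assert tri.clustering_coefficient == 1.0 and tri.mean_neighbors == 2.0
    star = network_stats(nx.star_graph(3))
    assert star.clustering_coefficient == 0.0
    assert np.isclose(star.mean_neighbors, 1.5)
    assert np.isclose(star.heterogeneity, np.sqrt(0.75) / 1.5)


def test_strip_functional_edges_never_grows_the_network():
    models = [_model("T1", ["a", "b"]),
              _model("T2", ["lin"], source="lineage")]
    g = build_network(models)
    stripped = strip_functional_edges(g)
    full = network_stats(g)
    sub = network_stats(stripped)
    assert sub.n_nodes <= full.n_nodes
    assert sub.mean_neighbors <= full.mean_neighbors


def test_compare_with_without_functional_flags_and_conventions():
    only_ceres = build_network([_model("T1", ["a", "b", "c"])])
    res = compare_with_without_functional(only_ceres)
    assert res["testable"] is False  # stripped network vanishes
    mixed = build_network([_model("T1", ["a", "b"]),
                           _model("T2", ["m1", "m2"], source="mutation_damaging")])
    res2 = compare_with_without_functional(mixed)
    assert res2["testable"] is True
    assert res2["with_functional"].n_edges > res2["without_functional"].n_edges
    # no CERES edges at all: nothing is stripped, identical stats, p = 1
    no_ceres = build_network([_model("T1", ["m1", "m2"],
                                     source="mutation_damaging")])
    res3 = compare_with_without_functional(no_ceres)
    assert res3["clustering_t_p"] == 1.0 and res3["neighbors_t_p"] == 1.0


def test_power_law_fit_exact_and_recovery():
    degrees = []
    for x in (2, 3, 4, 5):
        degrees += [x] * (3 * x ** 2)
    fit = power_law_fit(degrees)
    assert np.isclose(fit.a, 3.0, atol=1e-9) and np.isclose(fit.b, 2.0, atol=1e-9)
    assert np.isclose(fit.r2_loglog, 1.0)
    flat = [2] * 7 + [3] * 7 + [4] * 7
    f2 = power_law_fit(flat)
    assert np.isclose(f2.b, 0.0, atol=1e-9) and np.isclose(f2.a, 7.0)
    # planted exponent recovery from sampled degrees
    rng = np.random.default_rng(0)
    ks = np.arange(2, 51)
    p = ks ** -2.5 / (ks ** -2.5).sum()
    sample = rng.choice(ks, size=2000, p=p)
    rec = power_law_fit(sample)
    assert abs(rec.b + 2.5) < 0.3
    with pytest.raises(ValueError):
        power_law_fit([2, 2, 2])


def test_module_regression_identifies_the_generating_modules():
    rng = np.random.default_rng(1)
    n = 60
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    ceres = pd.DataFrame({
        "a1": a + 0.01 * rng.standard_normal(n), "a2": a,
        "b1": b, "b2": b + 0.01 * rng.standard_normal(n),
        "core1": a, "core2": a,
    })
    res = module_regression(ceres, ["a1", "a2"], ["b1", "b2"], ["core1", "core2"])
    assert np.isclose(res["A"]["coefficients"]["A"], 1.0, atol=0.05)
    assert res["A"]["coefficient_p"]["A"] < 1e-20
    assert res["A+B"]["aic"] - res["A"]["aic"] > -2  # B adds nothing


def test_module_regression_two_driver_case_over_seeds():
    hits = 0
    for s in range(10):
        rng = np.random.default_rng(100 + s)
        n = 80
        a, b = rng.standard_normal(n), rng.standard_normal(n)
        core = 0.5 * a + 0.5 * b + 0.1 * rng.standard_normal(n)
        ceres = pd.DataFrame({"a1": a, "b1": b, "c1": core})
        res = module_regression(ceres, ["a1"], ["b1"], ["c1"])
        sig = (res["A+B"]["coefficient_p"]["A"] < 0.01
               and res["A+B"]["coefficient_p"]["B"] < 0.01)
        best = (res["A+B"]["aic"] < min(res["A"]["aic"], res["B"]["aic"])
                and res["A+B"]["bic"] < min(res["A"]["bic"], res["B"]["bic"]))
        hits += sig and best
    assert hits == 10


def test_module_regression_input_errors():
    ceres = pd.DataFrame({"a": [1.0], "b": [2.0]})
    with pytest.raises(ValueError):
        module_regression(ceres, ["a"], ["b"], ["a"])
    ceres2 = pd.DataFrame({"a": np.arange(10.0), "b": np.arange(10.0)})
    with pytest.raises(KeyError):
        module_regression(ceres2, ["a"], ["missing"], ["b"])


def test_edge_density_permutation_bounds_and_depletion():
    n_perm = 199
    # depleted cross-edges between two anchored sets in a dense random graph
    rng = np.random.default_rng(0)
    g = nx.gnm_random_graph(40, 220, seed=2)
    set_a, set_b = list(range(0, 6)), list(range(6, 12))
    g.remove_edges_from([(u, v) for u, v in list(g.edges())
                         if (u in set_a and v in set_b)
                         or (u in set_b and v in set_a)])
    res = edge_density_permutation(g, set_a, set_b, n_perm=n_perm, seed=1)
    assert res["observed"] == 0
    assert res["p_value"] >= 1 / (n_perm + 1)
    assert res["p_value"] < 0.05
    # complete bipartite between the sets: depletion p ~ 1
    g2 = nx.gnm_random_graph(30, 120, seed=3)
    a2, b2 = list(range(0, 5)), list(range(5, 10))
    g2.add_edges_from([(u, v) for u in a2 for v in b2])
    res2 = edge_density_permutation(g2, a2, b2, n_perm=99, seed=4)
    assert res2["p_value"] > 0.5
    with pytest.raises(ValueError):
        edge_density_permutation(g2, [1, 2], [2, 3], n_perm=9, seed=0)
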