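#!/usr/bin/env python
"""Feature composition and the prediction network.

Pools the top-10 features across targets (composition per data source,
chi-squared against the input census, redundancy scores, relation classes
against the planted annotations), builds the feature->target network,
extracts Louvain communities, contrasts the network with and without
functional (CERES) edges, and fits the degree distribution power law.
"""

import ast
import json
from pathlib import Path

import pandas as pd

from depcompress import (assemble_features, build_network,
                         classify_feature_relation,
                         compare_with_without_functional,
                         feature_source_composition, load_depmap,
                         louvain_communities, power_law_fit, prune_features,
                         redundancy_score)
from depcompress.models import TargetModel
from depcompress.network import export_graphml
from depcompress.preprocess import FeatureDescriptor

DATA, OUT = Path("results/data"), Path("results/network")


def main() -> None:
    dataset = load_depmap(DATA)
    truth = json.loads((DATA / "ground_truth.json").read_text())
    feats = pd.read_csv("results/models/top10_features.csv", index_col=0)
    top10 = {g: [FeatureDescriptor(*t) for t in ast.literal_eval(row["features"])]
             for g, row in feats.iterrows()}
    OUT.mkdir(parents=True, exist_ok=True)

    census = prune_features(assemble_features(dataset, next(iter(top10)))).census()
    comp = feature_source_composition(top10, census)
    print("top-10 feature shares by source:",
          {k: round(float(v), 3) for k, v in comp["shares"].items() if v > 0})
    print(f"chi-squared vs input census: chi2={comp['chi2']:.1f}, "
          f"p={comp['chi2_p']:.3g} (CERES features are enriched)")
    redundancy = {s: redundancy_score(top10, s)
                  for s in ("CERES", "RNAseq", "CNV")}
    print("redundancy (uses per distinct feature):",
          {k: round(v, 2) for k, v in redundancy.items() if v == v})

    relations = []
    for gene, ds in top10.items():
        for d in ds:
            relations.append((gene, d.source, d.name,
                              classify_feature_relation(
                                  d, gene, paralog_map=truth["paralog_map"]).label))
    rel = pd.DataFrame(relations, columns=["target", "source", "feature", "relation"])
    rel.to_csv(OUT / "feature_relations.csv", index=False)
    print("relation classes:", rel["relation"].value_counts().to_dict())

    models = [TargetModel(g, "top10", ds, {d: 1.0 for d in ds}, None, 0)
              for g, ds in top10.items()]
    net = build_network(models)
    comm = louvain_communities(net, seed=0)
    export_graphml(net, OUT / "prediction_network.graphml", comm)
    res = compare_with_without_functional(net)
    w, wo = res["with_functional"], res["without_functional"]
    print(f"with functional edges: {w.n_nodes} nodes, mean neighbors "
          f"{w.mean_neighbors:.2f}, clustering {w.clustering_coefficient:.3f}")
    if wo is not None:
        print(f"without: {wo.n_nodes} nodes, mean neighbors "
              f"{wo.mean_neighbors:.2f}, clustering {wo.clustering_coefficient:.3f}"
              f" (t-test p: neighbors {res['neighbors_t_p']:.3g})")
    degrees = [d for _, d in net.to_undirected().degree()]
    try:
        fit = power_law_fit(degrees)
        print(f"degree power law y = a x^b: a={fit.a:.2f}, b={fit.b:.2f}, "
              f"log-log R^2={fit.r2_loglog:.2f}")
    except ValueError as exc:
        print(f"power-law fit skipped: {exc}")
    with open(OUT / "stats.json", "w") as fh:
        json.dump({"shares": comp["shares"], "chi2_p": comp["chi2_p"],
                   "redundancy": {k: v for k, v in redundancy.items() if v == v},
                   "n_communities": len(set(comm.values()))}, fh, indent=2)


if __name__ == "__main__":
    main()
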