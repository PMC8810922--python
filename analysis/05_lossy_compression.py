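#!/usr/bin/env python
"""Derive lossy landmark panels and reconstruct genome-scale profiles.

Splits cell lines into train/validation, derives tight-cluster centroid
panels across sizes (the saturation analysis), fits one compression forest
per gene from panel CERES features only, and reports reconstruction
fidelity overall, per essentiality class, and as top-hit overlap.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from depcompress import (ModelConfig, TightClusterParams, evaluate_compression,
                         extract_lossy, fit_compression_models, hit_overlap,
                         infer_genome, load_depmap, saturation_analysis,
                         tight_clusters)

DATA, OUT = Path("results/data"), Path("results/compression")
SIZES = [10, 20, 40, 60]
PANEL_SIZE = 40  # the planted factor count of the simulated release


def main() -> None:
    dataset = load_depmap(DATA)
    truth = json.loads((DATA / "ground_truth.json").read_text())
    ceres = dataset.ceres
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(ceres))
    val_cells = ceres.index[np.sort(perm[:45])]
    train_cells = ceres.index[np.sort(perm[45:])]
    train, val = ceres.loc[train_cells], ceres.loc[val_cells]
    OUT.mkdir(parents=True, exist_ok=True)

    params = TightClusterParams(seed=1)
    cfg = ModelConfig(n_trees=50, seed=2)
    eval_genes = sorted(rng.choice(ceres.columns, size=400, replace=False))
    curve = saturation_analysis(train, val, SIZES, params, cfg,
                                eval_genes=eval_genes)
    print("saturation curve (panel size -> validation r):",
          {k: round(v, 3) for k, v in curve.items()})

    panel = tight_clusters(train, PANEL_SIZE, params)
    pd.DataFrame([(g, c) for c in panel.genes for g in panel.cluster_members[c]],
                 columns=["gene", "centroid"]).to_csv(OUT / "lossy_set.csv",
                                                      index=False)
    store = fit_compression_models(train, panel, cfg)
    pred = infer_genome(store, val[panel.genes])
    report = evaluate_compression(pred, val, truth["gene_class"])
    print(f"panel of {PANEL_SIZE} centroids reconstructs {pred.shape[1]} genes "
          f"on {len(val)} held-out lines: overall r = {report.pearson_overall:.3f}")
    print("per-class r:", {k: round(v, 3) for k, v in report.pearson_by_class.items()})

    # hit overlap for one held-out line, using panel measurements only
    cell = val.index[0]
    measured = extract_lossy(val.loc[cell], panel)
    inferred = infer_genome(store, measured.to_frame().T).loc[cell]
    n_top = 100
    overlap = hit_overlap(inferred, val.loc[cell], n_top=n_top,
                          reference_means=train.mean())
    print(f"top-{n_top} differentially-required hit overlap for {cell}: "
          f"{overlap}/{n_top}")
    with open(OUT / "compression_report.json", "w") as fh:
        json.dump({"saturation_curve": curve,
                   "pearson_overall": report.pearson_overall,
                   "pearson_by_class": report.pearson_by_class,
                   "hit_overlap": [n_top, int(overlap)]}, fh, indent=2)


if __name__ == "__main__":
    main()
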