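#!/usr/bin/env python
"""Generate the planted multi-omic release used by the downstream analyses.

Writes a DepMap-dialect table set (gene effect, expression, copy number,
mutations, sample info, 2-D embedding) plus the planted ground truth under
results/data/, and prints a census of what was planted.
"""

import json
from pathlib import Path

from depcompress import GeneratorConfig, generate_dataset, write_depmap_tables

OUT = Path("results/data")


def main() -> None:
    cfg = GeneratorConfig(seed=42)
    dataset, truth = generate_dataset(cfg)
    write_depmap_tables(dataset, OUT)
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump({
            "gene_class": truth.gene_class,
            "cluster_assignment": truth.cluster_assignment,
            "centroid_gene": {str(k): v for k, v in truth.centroid_gene.items()},
            "paralog_map": truth.paralog_map,
            "planted_predictors": {
                g: [[d.source, d.name, rel] for d, rel in preds]
                for g, preds in truth.planted_predictors.items()},
        }, fh, indent=2)

    classes = {c: len(truth.genes_of_class(c))
               for c in ("common_essential", "selective", "nonessential")}
    n_planted = sum(len(v) for v in truth.planted_predictors.values())
    print(f"wrote {dataset.ceres.shape[0]} cell lines x "
          f"{dataset.ceres.shape[1]} genes to {OUT}")
    print(f"gene classes: {classes}")
    print(f"{cfg.n_factors} latent pathway factors; "
          f"{n_planted} planted predictor relations "
          f"(functional, paralog, synthetic-lethal, dosage, lineage)")


if __name__ == "__main__":
    main()
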