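#!/usr/bin/env python
"""Assemble the analysis outputs into one summary bundle.

Collects the target census, model evaluation, network statistics, and
compression report written by the earlier scripts into
results/summary.json, and prints the headline numbers.
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path("results")


def main() -> None:
    bundle = {}
    targets = pd.read_csv(RESULTS / "targets" / "context_specific.csv")
    bundle["n_context_specific_targets"] = int(len(targets))
    ev = pd.read_csv(RESULTS / "models" / "evaluation.csv")
    bundle["n_models"] = int(len(ev))
    bundle["mean_top10_r2"] = float(ev["r2_top10"].mean())
    bundle["mean_recall"] = float(ev["recall"].mean())
    bundle["multivariate_win_fraction"] = float(
        (ev["r2_top10"] > ev["r2_best_univariate"]).mean())
    for part, fname in (("network", "network/stats.json"),
                        ("compression", "compression/compression_report.json")):
        p = RESULTS / fname
        if p.exists():
            bundle[part] = json.loads(p.read_text())
    with open(RESULTS / "summary.json", "w") as fh:
        json.dump(bundle, fh, indent=2)
    print(json.dumps(bundle, indent=2))


if __name__ == "__main__":
    main()
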