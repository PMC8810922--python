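"""Staged, cached execution of the whole analysis.

Stages form a linear DAG: simulate|ingest -> preprocess -> train -> evaluate
-> network -> compress -> report. Each stage writes its outputs plus a
content hash of its effective configuration (chained with the upstream
hash); re-running with an unchanged configuration is a no-op on cached
stages. One global seed determines every stochastic choice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import zlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compression, evaluation, network as net
from .datasets import MultiOmicDataset, load_depmap, write_depmap_tables
from .models import ModelConfig, build_target_models
from .preprocess import PreprocessConfig, select_context_specific
from .synthetic import GeneratorConfig, generate_dataset

STAGES = ("simulate", "preprocess", "train", "evaluate", "network", "compress", "report")


@dataclass
class CompressionConfig:
    sizes: list[int] = field(default_factory=lambda: [25, 75, 100, 200, 300])
    tight: compression.TightClusterParams = field(
        default_factory=compression.TightClusterParams)
    n_trees: int = 200
    validation_fraction: float = 0.15


@dataclass
class PipelineConfig:
    output_dir: str = "results/run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    input_path: str | None = None  # None -> simulate
    seed: int = 0
    scale: str = "desk"
    max_targets: int | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    compress: CompressionConfig = field(default_factory=CompressionConfig)

    def __post_init__(self) -> None:
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order) or order != list(range(order[0], order[0] + len(order))):
            raise ValueError(f"stages must form a contiguous prefix-run of {STAGES}")

    @classmethod
    def desk(cls, seed: int = 0, output_dir: str = "results/desk") -> "PipelineConfig":
        """A minutes-scale preset on simulated data."""
        gen = GeneratorConfig(n_cells=80, n_genes=160, n_factors=8,
                              n_synthetic_lethal=3, n_dosage=3, n_paralog_pairs=3,
                              n_lineages=4, n_lineage_effects=3, rare_category_size=5,
                              seed=seed)
        model = ModelConfig(n_trees=60, boruta_max_iter=25, seed=seed)
        comp = CompressionConfig(sizes=[4, 8],
                                 tight=compression.TightClusterParams(seed=seed),
                                 n_trees=60)
        return cls(output_dir=output_dir, seed=seed, scale="desk", max_targets=6,
                   generator=gen, model=model, compress=comp)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls.desk(seed=raw.get("seed", 0)) if raw.get("scale", "desk") == "desk" \
            else cls(seed=raw.get("seed", 0))
        for key in ("output_dir", "stages", "input_path", "max_targets", "scale"):
            if key in raw:
                setattr(cfg, key, raw[key])
        for key in ("generator", "preprocess", "model"):
            if key in raw:
                setattr(cfg, key, dataclasses.replace(getattr(cfg, key), **raw[key]))
        if "compress" in raw:
            c = raw["compress"]
            tight = dataclasses.replace(cfg.compress.tight, **c.pop("tight", {}))
            cfg.compress = dataclasses.replace(cfg.compress, tight=tight, **c)
        return cfg


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    return obj


def _gene_seed(base: int, gene: str) -> int:
    """Stable per-target seed derived from the global seed."""
    return (base * 100003 + zlib.crc32(gene.encode())) % (2**31 - 1)


def _hash(payload) -> str:
    return hashlib.sha256(json.dumps(_to_jsonable(payload), sort_keys=True)
                          .encode()).hexdigest()[:16]


class PipelineRun:
    """Executes stages against one output directory, with caching."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"stages": {}, "seed": config.seed}
        self._dataset: MultiOmicDataset | None = None
        self._truth = None
        self._bundles: dict = {}
        self._records: list = []
        self._network = None

    # -- caching helpers ---------------------------------------------------
    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(exist_ok=True)
        return d

    def _cached(self, stage: str, h: str) -> bool:
        f = self.outdir / stage / ".hash"
        return f.exists() and f.read_text() == h

    def _mark(self, stage: str, h: str) -> None:
        (self.outdir / stage / ".hash").write_text(h)

    def _log(self, stage: str, **info) -> None:
        entry = {"stage": stage, "time": time.time(), **_to_jsonable(info)}
        with open(self.outdir / "log.jsonl", "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    # -- stages ------------------------------------------------------------
    def simulate(self) -> None:
        h = _hash(("simulate", self.config.generator))
        d = self._stage_dir("simulate")
        if not self._cached("simulate", h):
            dataset, truth = generate_dataset(self.config.generator)
            write_depmap_tables(dataset, d / "tables")
            with open(d / "ground_truth.json", "w") as fh:
                json.dump({
                    "gene_class": truth.gene_class,
                    "cluster_assignment": truth.cluster_assignment,
                    "centroid_gene": {str(k): v for k, v in truth.centroid_gene.items()},
                    "paralog_map": truth.paralog_map,
                    "planted_predictors": {
                        g: [[d_.source, d_.name, rel] for d_, rel in preds]
                        for g, preds in truth.planted_predictors.items()},
                }, fh, indent=2)
            self._mark("simulate", h)
            self._log("simulate", cached=False)
        self._dataset = load_depmap(d / "tables")
        self.manifest["stages"]["simulate"] = h

    def ingest(self) -> None:
        self._dataset = load_depmap(self.config.input_path)
        self.manifest["stages"]["ingest"] = _hash(("ingest", self.config.input_path))

    @property
    def dataset(self) -> MultiOmicDataset:
        if self._dataset is None:
            raise RuntimeError("no dataset loaded: run simulate/ingest first")
        return self._dataset

    def preprocess_stage(self) -> list[str]:
        h = _hash(("preprocess", self.manifest["stages"].get("simulate"),
                   self.config.preprocess))
        d = self._stage_dir("preprocess")
        path = d / "context_targets.csv"
        if not (self._cached("preprocess", h) and path.exists()):
            targets = select_context_specific(self.dataset.ceres, self.config.preprocess)
            pd.Series(targets, name="gene").to_csv(path, index=False)
            self._mark("preprocess", h)
            self._log("preprocess", n_targets=len(targets))
        self.manifest["stages"]["preprocess"] = h
        return pd.read_csv(path)["gene"].tolist()

    def train(self) -> None:
        targets = self.preprocess_stage()
        if self.config.max_targets is not None:
            rng = np.random.default_rng(self.config.seed)
            if len(targets) > self.config.max_targets:
                targets = sorted(rng.choice(targets, size=self.config.max_targets,
                                            replace=False))
        h = _hash(("train", self.manifest["stages"]["preprocess"], targets,
                   self.config.model))
        d = self._stage_dir("train")
        sidecar = d / "models.json"
        if self._cached("train", h) and sidecar.exists():
            self.manifest["stages"]["train"] = h
            self.manifest["train_cached"] = True
            with open(sidecar) as fh:
                self._train_sidecar = json.load(fh)
            # refits are still needed in-memory for evaluate when not cached there
            self._bundles = {}
            return
        side = {}
        for gene in targets:
            cfg = replace(self.config.model, seed=_gene_seed(self.config.model.seed, gene))
            bundle = build_target_models(self.dataset, gene, cfg, self.config.preprocess)
            self._bundles[gene] = bundle
            side[gene] = {
                "predictable": bundle.predictable,
                "confirmed": [list(f) for f in bundle.confirmed],
                "top10": [list(f) for f in (bundle.top10.features if bundle.top10 else [])],
            }
        with open(sidecar, "w") as fh:
            json.dump(side, fh, indent=2)
        self._train_sidecar = side
        self._mark("train", h)
        self._log("train", n_models=len(side))
        self.manifest["stages"]["train"] = h
        self.manifest["train_cached"] = False

    def _ensure_bundles(self) -> None:
        if not self._bundles:
            self.manifest["train_cached"] = False
            targets = list(self._train_sidecar)
            for gene in targets:
                cfg = replace(self.config.model,
                              seed=_gene_seed(self.config.model.seed, gene))
                self._bundles[gene] = build_target_models(
                    self.dataset, gene, cfg, self.config.preprocess)

    def evaluate(self) -> pd.DataFrame:
        h = _hash(("evaluate", self.manifest["stages"]["train"]))
        d = self._stage_dir("evaluate")
        path = d / "evaluation.csv"
        if self._cached("evaluate", h) and path.exists():
            self.manifest["stages"]["evaluate"] = h
            return pd.read_csv(path)
        self._ensure_bundles()
        rows = []
        for gene, bundle in self._bundles.items():
            if not bundle.predictable:
                continue
            test = bundle.split.test_cells
            y_test = self.dataset.ceres.loc[test, gene].to_numpy()
            test_table = bundle.table.values.loc[test]
            train = bundle.split.train_cells
            y_train = self.dataset.ceres.loc[train, gene].to_numpy()
            for variant, model in (("full", bundle.full), ("reduced", bundle.reduced),
                                   ("top10", bundle.top10)):
                pred = model.estimator.predict(
                    test_table[[f.key for f in model.features]].to_numpy())
                r2_cv = np.nan
                if variant in ("reduced", "top10"):
                    from sklearn.base import clone
                    X_tr = bundle.table.values.loc[
                        train, [f.key for f in model.features]].to_numpy()
                    r2_cv = evaluation.cross_validated_r2(
                        lambda m=model: clone(m.estimator), X_tr, y_train,
                        seed=self.config.seed)
                rec = evaluation.EvaluationRecord(
                    target_gene=gene, variant=variant,
                    r2_cv=r2_cv,
                    r2_test=evaluation.r_squared(y_test, pred),
                    recall=evaluation.recall_metric(
                        pred, self.dataset.ceres.loc[test], gene,
                        n_null=200, seed=self.config.seed),
                    concordance=evaluation.concordance(y_test, pred),
                )
                rows.append(asdict(rec))
        df = pd.DataFrame(rows)
        df.to_csv(path, index=False)
        # predictable-target filter: recall/CV-R^2 thresholds + a working univariate
        best_uni = {}
        for gene, bundle in self._bundles.items():
            if not bundle.univariates:
                continue
            test = bundle.split.test_cells
            y_t = self.dataset.ceres.loc[test, gene].to_numpy()
            Xt = bundle.table.values.loc[test]
            best_uni[gene] = max(
                evaluation.r_squared(
                    y_t, m.estimator.predict(Xt[[m.features[0].key]].to_numpy()))
                for m in bundle.univariates.values())
        records = [evaluation.EvaluationRecord(**{k: r[k] for k in r})
                   for r in rows]
        predictable = evaluation.filter_predictable(records, best_uni)
        pd.Series(sorted(predictable), name="gene").to_csv(
            d / "predictable.csv", index=False)
        self._mark("evaluate", h)
        self._log("evaluate", n_records=len(df))
        self.manifest["stages"]["evaluate"] = h
        return df

    def network_stage(self) -> None:
        h = _hash(("network", self.manifest["stages"]["train"]))
        d = self._stage_dir("network")
        if self._cached("network", h) and (d / "stats.json").exists():
            self.manifest["stages"]["network"] = h
            return
        self._ensure_bundles()
        top10 = [b.top10 for b in self._bundles.values() if b.top10 is not None]
        if not top10:
            stats = {"note": "no predictable targets; empty network"}
        else:
            g = net.build_network(top10)
            comm = net.louvain_communities(g, seed=self.config.seed)
            net.export_graphml(g, d / "prediction_network.graphml", comm)
            full = net.network_stats(g)
            stats = {"with_functional": _to_jsonable(full)}
            if any(e.get("source") == "CERES" for _, _, e in g.edges(data=True)):
                stats["comparison"] = _to_jsonable(net.compare_with_without_functional(g))
        with open(d / "stats.json", "w") as fh:
            json.dump(_to_jsonable(stats), fh, indent=2)
        self._mark("network", h)
        self._log("network")
        self.manifest["stages"]["network"] = h

    def compress_stage(self) -> None:
        cfg = self.config.compress
        h = _hash(("compress", self.manifest["stages"].get("simulate"), cfg))
        d = self._stage_dir("compress")
        if self._cached("compress", h) and (d / "compression_report.json").exists():
            self.manifest["stages"]["compress"] = h
            return
        ceres = self.dataset.ceres
        rng = np.random.default_rng(self.config.seed)
        n_val = max(2, int(round(cfg.validation_fraction * len(ceres))))
        perm = rng.permutation(len(ceres))
        val_cells = ceres.index[sorted(perm[:n_val])]
        train_cells = ceres.index[sorted(perm[n_val:])]
        model_cfg = replace(self.config.model, n_trees=cfg.n_trees)
        curve = compression.saturation_analysis(
            ceres.loc[train_cells], ceres.loc[val_cells], cfg.sizes, cfg.tight,
            model_cfg)
        best = max(curve, key=curve.get)
        lset = compression.tight_clusters(ceres.loc[train_cells], best, cfg.tight)
        pd.DataFrame([(g, c) for c in lset.genes for g in lset.cluster_members[c]],
                     columns=["gene", "cluster"]).to_csv(d / "lossy_set.csv", index=False)
        store = compression.fit_compression_models(ceres.loc[train_cells], lset,
                                                   model_cfg)
        pred = compression.infer_genome(store, ceres.loc[val_cells, lset.genes])
        report = compression.evaluate_compression(pred, ceres.loc[val_cells])
        payload = {"saturation_curve": {str(k): v for k, v in curve.items()},
                   "selected_size": best,
                   "pearson_overall": report.pearson_overall}
        with open(d / "compression_report.json", "w") as fh:
            json.dump(_to_jsonable(payload), fh, indent=2)
        self._mark("compress", h)
        self._log("compress", **payload)
        self.manifest["stages"]["compress"] = h

    def report(self) -> dict:
        bundle: dict = {"seed": self.config.seed, "scale": self.config.scale}
        eval_path = self.outdir / "evaluate" / "evaluation.csv"
        if eval_path.exists():
            df = pd.read_csv(eval_path)
            bundle["n_evaluation_records"] = int(len(df))
            if len(df):
                top10 = df[df["variant"] == "top10"]
                bundle["mean_top10_r2_test"] = float(top10["r2_test"].mean())
                bundle["mean_top10_recall"] = float(top10["recall"].mean())
        for stage, fname in (("network", "stats.json"),
                             ("compress", "compression_report.json")):
            p = self.outdir / stage / fname
            if p.exists():
                with open(p) as fh:
                    bundle[stage] = json.load(fh)
        with open(self.outdir / "report.json", "w") as fh:
            json.dump(bundle, fh, indent=2)
        self.manifest["stages"]["report"] = _hash(bundle)
        return bundle


def run(config: PipelineConfig) -> dict:
    """Execute the requested stages; returns the run manifest."""
    r = PipelineRun(config)
    t0 = time.time()
    for stage in config.stages:
        if stage == "simulate":
            r.simulate() if config.input_path is None else r.ingest()
        elif stage == "preprocess":
            r.preprocess_stage()
        elif stage == "train":
            r.train()
        elif stage == "evaluate":
            r.evaluate()
        elif stage == "network":
            r.network_stage()
        elif stage == "compress":
            r.compress_stage()
        elif stage == "report":
            r.report()
    r.manifest["wall_time_s"] = time.time() - t0
    with open(r.outdir / "manifest.json", "w") as fh:
        json.dump(_to_jsonable(r.manifest), fh, indent=2)
    return r.manifest
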