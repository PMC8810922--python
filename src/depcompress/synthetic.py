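"""DepMap-like synthetic multi-omic data with planted, recoverable structure.

The generator emulates the statistical regime of a gene-effect (CERES)
release: common essential genes centered near -1, nonessential genes near 0,
and selective genes whose scores are continuous linear readouts of shared
latent pathway factors (a common genetic architecture). On top of the shared
factors it plants the private mechanisms the models are meant to discover:
mutation-driven synthetic lethality, own-expression dosage effects, paralog
pairs, and lineage-restricted effects. Accompanying expression / copy-number
/ mutation / lineage tables and a 2-D embedding make the output a drop-in
DepMap-dialect release, and a :class:`GroundTruth` records every planted
effect for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import MultiOmicDataset
from .preprocess import FeatureDescriptor

CLASS_MEANS = {"common_essential": -1.0, "selective": -0.3, "nonessential": 0.0}


@dataclass
class GeneratorConfig:
    """Knobs of the planted data-generating process.

    ``class_fractions`` is (common_essential, selective, nonessential) and
    must sum to 1. ``loading_scale`` sets the typical magnitude of a selective
    gene's loading on its latent factor (CERES units per factor SD);
    ``noise_sd`` is the i.i.d. measurement noise on every CERES entry.
    ``rare_category_size`` forces one lineage to have exactly that many cells,
    exercising the <=10-support indicator pruning rule.
    """
    n_cells: int = 300
    n_genes: int = 1200
    n_factors: int = 40
    class_fractions: tuple[float, float, float] = (0.20, 0.35, 0.45)
    loading_scale: float = 0.6
    noise_sd: float = 0.15
    n_synthetic_lethal: int = 10
    mutation_effect: float = -0.8
    n_dosage: int = 10
    dosage_effect: float = -0.5
    n_paralog_pairs: int = 10
    n_lineages: int = 8
    n_lineage_effects: int = 8
    lineage_effect: float = -0.7
    lineage_factor_sd: float = 0.5
    rare_category_size: int = 8
    nonexpressed_fraction: float = 0.10
    seed: int = 42

    def validate(self) -> None:
        counts = ("n_cells", "n_genes", "n_factors", "n_synthetic_lethal", "n_dosage",
                  "n_paralog_pairs", "n_lineages", "n_lineage_effects", "rare_category_size")
        for name in counts:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if self.class_fractions[1] > 0 and self.n_factors < 1:
            raise ValueError("n_factors must be >= 1 when the selective fraction is positive")
        n_special = (2 * self.n_paralog_pairs + self.n_synthetic_lethal
                     + self.n_dosage + self.n_lineage_effects)
        n_sel = round(self.class_fractions[1] * self.n_genes)
        if n_special > n_sel:
            raise ValueError(
                f"n_genes too small to host all planted effects: "
                f"{n_special} special roles but only {n_sel} selective genes")


@dataclass
class GroundTruth:
    """Everything that was planted, for recovery oracles."""
    gene_class: dict[str, str]
    factor_loadings: pd.DataFrame  # gene x factor
    planted_predictors: dict[str, list[tuple[FeatureDescriptor, str]]]
    cluster_assignment: dict[str, int]  # selective gene -> factor index
    centroid_gene: dict[int, str]  # factor index -> largest-|loading| gene
    paralog_map: dict[str, str] = field(default_factory=dict)

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]


def generate_dataset(config: GeneratorConfig | None = None
                     ) -> tuple[MultiOmicDataset, GroundTruth]:
    """Draw one synthetic multi-omic release. Deterministic given the seed.

    CERES[c, g] = class_mean(g) + sum_k L[g, k] * F[c, k]
                  + mutation / dosage / lineage terms + N(0, noise_sd).
    Latent factors are standard normal with a per-lineage mean shift, so
    lineage indicators carry genuine signal.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    cells = pd.Index([f"ACH-{900000 + i}" for i in range(1, config.n_cells + 1)],
                     name="DepMap_ID")
    entrez = {g: 100000 + i for i, g in enumerate(genes, start=1)}

    # --- gene classes -----------------------------------------------------
    f_ce, f_sel, _ = config.class_fractions
    n_ce = round(f_ce * config.n_genes)
    n_sel = round(f_sel * config.n_genes)
    order = rng.permutation(config.n_genes)
    ce_genes = [genes[i] for i in order[:n_ce]]
    sel_genes = [genes[i] for i in order[n_ce:n_ce + n_sel]]
    ne_genes = [genes[i] for i in order[n_ce + n_sel:]]
    gene_class = {g: "common_essential" for g in ce_genes}
    gene_class.update({g: "selective" for g in sel_genes})
    gene_class.update({g: "nonessential" for g in ne_genes})

    # --- lineages ---------------------------------------------------------
    lineage_labels = [f"lineage_{k:02d}" for k in range(config.n_lineages)]
    lin_idx = np.zeros(config.n_cells, dtype=int)
    if config.n_lineages > 1:
        rare = config.n_lineages - 1
        common = np.arange(config.n_lineages - 1)
        lin_idx = rng.integers(0, len(common), size=config.n_cells)
        if 0 < config.rare_category_size < config.n_cells:
            rare_cells = rng.choice(config.n_cells, size=config.rare_category_size,
                                    replace=False)
            lin_idx[rare_cells] = rare
    lineage = pd.Series([lineage_labels[i] for i in lin_idx], index=cells, name="lineage")

    # --- latent factors (lineage-linked) ----------------------------------
    n_fac = max(config.n_factors, 1)
    shift = rng.normal(0.0, config.lineage_factor_sd, size=(config.n_lineages, n_fac))
    F = rng.standard_normal((config.n_cells, n_fac)) + shift[lin_idx]

    # --- selective-gene loadings ------------------------------------------
    loadings = np.zeros((config.n_genes, n_fac))
    gene_pos = {g: i for i, g in enumerate(genes)}
    cluster_assignment: dict[str, int] = {}
    factor_members: dict[int, list[str]] = {k: [] for k in range(n_fac)}
    for i, g in enumerate(sel_genes):
        k = i % config.n_factors if config.n_factors else 0
        # co-functional genes load with a common sign; anticorrelation enters
        # only through the planted paralog pairs below
        loadings[gene_pos[g], k] = config.loading_scale * rng.uniform(0.7, 1.3)
        cluster_assignment[g] = k
        factor_members[k].append(g)

    planted: dict[str, list[tuple[FeatureDescriptor, str]]] = {g: [] for g in genes}

    # --- paralog pairs: same factor, anticorrelated loadings ---------------
    special = iter(sel_genes)
    paralog_map: dict[str, str] = {}
    for _ in range(config.n_paralog_pairs):
        a = next(special)
        b = next(special)
        kb = cluster_assignment[a]  # move b onto a's factor, anticorrelated
        loadings[gene_pos[b], cluster_assignment[b]] = 0.0
        loadings[gene_pos[b], kb] = -np.sign(loadings[gene_pos[a], kb]) * abs(
            config.loading_scale * rng.uniform(0.7, 1.3))
        if b in factor_members[cluster_assignment[b]]:
            factor_members[cluster_assignment[b]].remove(b)
        factor_members[kb].append(b)
        cluster_assignment[b] = kb
        paralog_map[a] = b
        paralog_map[b] = a
        planted[a].append((FeatureDescriptor("CERES", b), "paralog"))
        planted[b].append((FeatureDescriptor("CERES", a), "paralog"))

    # --- synthetic lethality: damaging mutation in a partner gene ----------
    sl_targets = [next(special) for _ in range(config.n_synthetic_lethal)]
    sl_partner = {t: ne_genes[i] for i, t in enumerate(sl_targets)}
    sl_calls = {t: rng.binomial(1, 0.15, size=config.n_cells) for t in sl_targets}
    for t in sl_targets:
        planted[t].append((FeatureDescriptor("mutation_damaging", sl_partner[t]),
                           "synthetic_lethal"))

    # --- dosage: own expression drives CERES -------------------------------
    dosage_targets = [next(special) for _ in range(config.n_dosage)]
    for t in dosage_targets:
        planted[t].append((FeatureDescriptor("RNAseq", t), "dosage"))

    # --- lineage effects ----------------------------------------------------
    lineage_targets = [next(special) for _ in range(config.n_lineage_effects)]
    n_common_lin = max(config.n_lineages - 1, 1)
    lin_for_target = {t: i % n_common_lin for i, t in enumerate(lineage_targets)}
    for t in lineage_targets:
        planted[t].append((FeatureDescriptor("lineage", lineage_labels[lin_for_target[t]]),
                           "lineage"))

    # --- functional (shared-factor) predictors ------------------------------
    centroid_gene: dict[int, str] = {}
    for k, members in factor_members.items():
        if not members:
            continue
        mags = {g: abs(loadings[gene_pos[g], k]) for g in members}
        centroid_gene[k] = max(members, key=lambda g: (mags[g], g))
    for g in sel_genes:
        k = cluster_assignment[g]
        partner = centroid_gene.get(k)
        if partner == g:
            others = [m for m in factor_members[k] if m != g]
            partner = max(others, key=lambda m: (abs(loadings[gene_pos[m], k]), m)) \
                if others else None
        if partner is not None:
            planted[g].append((FeatureDescriptor("CERES", partner), "functional"))

    # --- expression ---------------------------------------------------------
    n_nonexpr = round(config.nonexpressed_fraction * config.n_genes)
    nonexpr_pool = [g for g in genes if g not in dosage_targets]
    nonexpr = set(rng.choice(nonexpr_pool, size=min(n_nonexpr, len(nonexpr_pool)),
                             replace=False))
    base_expr = rng.normal(4.0, 1.0, size=config.n_genes)
    expr_shift = rng.normal(0.0, 0.3, size=(config.n_lineages, config.n_genes))
    logtpm = base_expr[None, :] + expr_shift[lin_idx] \
        + rng.normal(0.0, 0.5, size=(config.n_cells, config.n_genes))
    extra = rng.normal(0.0, 1.0, size=(config.n_cells, len(dosage_targets)))
    for j, t in enumerate(dosage_targets):
        logtpm[:, gene_pos[t]] += extra[:, j]
    nonexpr_tpm = rng.uniform(0.0, 0.8, size=(config.n_cells, len(nonexpr)))
    for j, g in enumerate(sorted(nonexpr)):
        logtpm[:, gene_pos[g]] = np.log2(1.0 + nonexpr_tpm[:, j])
    tpm = np.maximum(np.power(2.0, logtpm) - 1.0, 0.0)

    # --- copy number (decoy channel, no planted effects) --------------------
    cn = np.clip(rng.normal(1.0, 0.15, size=(config.n_cells, config.n_genes)), 0.0, None)

    # --- mutations -----------------------------------------------------------
    mut = {cls: np.zeros((config.n_cells, config.n_genes), dtype=np.int8)
           for cls in ("damaging", "hotspot_nondamaging", "other")}
    for cls, frac, rate in (("damaging", 0.15, 0.05),
                            ("hotspot_nondamaging", 0.10, 0.05),
                            ("other", 0.15, 0.05)):
        decoys = rng.choice(config.n_genes, size=round(frac * config.n_genes), replace=False)
        mut[cls][:, decoys] = rng.binomial(1, rate, size=(config.n_cells, len(decoys)))
    # a thin tail of very rare calls exercises the <=10-support pruning rule
    rare_decoys = rng.choice(config.n_genes, size=max(config.n_genes // 50, 1), replace=False)
    mut["damaging"][:, rare_decoys] = rng.binomial(
        1, 0.01, size=(config.n_cells, len(rare_decoys)))
    for t in sl_targets:
        mut["damaging"][:, gene_pos[sl_partner[t]]] = sl_calls[t]

    # --- CERES ----------------------------------------------------------------
    class_mean = np.array([CLASS_MEANS[gene_class[g]] for g in genes])
    ceres = class_mean[None, :] + F @ loadings.T
    for t in sl_targets:
        ceres[:, gene_pos[t]] += config.mutation_effect * sl_calls[t]
    for j, t in enumerate(dosage_targets):
        col = logtpm[:, gene_pos[t]]
        z = (col - col.mean()) / col.std(ddof=1)
        ceres[:, gene_pos[t]] += config.dosage_effect * z
    for t in lineage_targets:
        ceres[:, gene_pos[t]] += config.lineage_effect * (lin_idx == lin_for_target[t])
    if config.noise_sd > 0:
        ceres = ceres + rng.normal(0.0, config.noise_sd, size=ceres.shape)

    # --- 2-D embedding: leading principal directions of the omics -------------
    omics = np.hstack([logtpm, cn])
    omics = omics - omics.mean(axis=0)
    sd = omics.std(axis=0)
    omics = omics[:, sd > 0] / sd[sd > 0]
    u, s, _ = np.linalg.svd(omics, full_matrices=False)
    emb = u[:, :2] * s[:2]
    embedding = pd.DataFrame(emb, index=cells, columns=["umap_1", "umap_2"])

    dataset = MultiOmicDataset(
        ceres=pd.DataFrame(ceres, index=cells, columns=genes),
        expression=pd.DataFrame(tpm, index=cells, columns=genes),
        copy_number=pd.DataFrame(cn, index=cells, columns=genes),
        mutations={cls: pd.DataFrame(m, index=cells, columns=genes)
                   for cls, m in mut.items()},
        lineage=lineage,
        embedding2d=embedding,
        release_tag=f"synthetic-seed{config.seed}",
        entrez=entrez,
    )
    truth = GroundTruth(
        gene_class=gene_class,
        factor_loadings=pd.DataFrame(loadings, index=genes,
                                     columns=[f"F{k}" for k in range(n_fac)]),
        planted_predictors={g: preds for g, preds in planted.items() if preds},
        cluster_assignment=cluster_assignment,
        centroid_gene=centroid_gene,
        paralog_map=paralog_map,
    )
    return dataset, truth
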