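"""Feature assembly and the cleaning/pruning/normalization rules.

A design matrix for one target gene concatenates, per cell line: the CERES
scores of every other gene, log-scale expression, copy number, three classes
of mutation indicators, and one-hot lineage. Pruning removes uninformative
columns (constants, rare indicator categories, never-expressed transcripts);
normalization z-scores only the continuous omics (expression, copy number),
with statistics taken from a designated cell subset so that held-out cells
never leak into the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import MultiOmicDataset

#: feature sources, in assembly order
SOURCES = ("CERES", "RNAseq", "CNV", "mutation_damaging", "mutation_hotspot",
           "mutation_other", "lineage")

_MUTATION_SOURCE = {
    "damaging": "mutation_damaging",
    "hotspot_nondamaging": "mutation_hotspot",
    "other": "mutation_other",
}

INDICATOR_SOURCES = ("mutation_damaging", "mutation_hotspot", "mutation_other", "lineage")


class FeatureDescriptor(NamedTuple):
    source: str
    name: str

    @property
    def key(self) -> str:
        return f"{self.source}:{self.name}"


@dataclass
class PreprocessConfig:
    """Thresholds for target selection and feature pruning.

    sd_threshold / range_threshold are in CERES units and select
    context-specific target genes; tpm_threshold (TPM) drops never-expressed
    transcripts; indicator columns supported by <= min_category_support cells
    are removed.
    """
    sd_threshold: float = 0.25
    range_threshold: float = 0.6
    tpm_threshold: float = 1.0
    min_category_support: int = 10

    def __post_init__(self) -> None:
        for name in ("sd_threshold", "range_threshold", "tpm_threshold", "min_category_support"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FeatureTable:
    """Cell x feature design matrix for one target gene.

    ``values`` columns are keyed ``"source:name"`` and stay aligned with
    ``descriptors``. Expression columns hold log2(TPM+1); pruning thresholds
    are converted to that scale.
    """
    values: pd.DataFrame
    descriptors: list[FeatureDescriptor]
    target_gene: str
    normalization_state: str = "raw"

    def __post_init__(self) -> None:
        if len(self.descriptors) != self.values.shape[1]:
            raise ValueError("descriptor count != column count")
        keys = [d.key for d in self.descriptors]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate feature descriptors")

    def subset(self, descriptors: Iterable[FeatureDescriptor]) -> "FeatureTable":
        descriptors = list(descriptors)
        cols = [d.key for d in descriptors]
        return FeatureTable(self.values[cols], descriptors, self.target_gene,
                            self.normalization_state)

    def census(self) -> dict[str, int]:
        """Feature count per source."""
        out: dict[str, int] = {}
        for d in self.descriptors:
            out[d.source] = out.get(d.source, 0) + 1
        return out


def assemble_features(dataset: MultiOmicDataset, target_gene: str) -> FeatureTable:
    """Build the raw design matrix for one target gene.

    The target's own CERES column is excluded; its own expression, copy-number
    and mutation columns are retained (they carry the same-gene dosage
    relation).
    """
    if target_gene not in dataset.ceres.columns:
        raise KeyError(f"unknown target gene {target_gene!r}")
    blocks: list[pd.DataFrame] = []
    descriptors: list[FeatureDescriptor] = []

    ceres = dataset.ceres.drop(columns=[target_gene])
    blocks.append(ceres)
    descriptors += [FeatureDescriptor("CERES", g) for g in ceres.columns]

    logtpm = np.log2(dataset.expression + 1.0)
    blocks.append(logtpm)
    descriptors += [FeatureDescriptor("RNAseq", g) for g in logtpm.columns]

    blocks.append(dataset.copy_number)
    descriptors += [FeatureDescriptor("CNV", g) for g in dataset.copy_number.columns]

    for cls, source in _MUTATION_SOURCE.items():
        mat = dataset.mutations[cls]
        blocks.append(mat.astype(float))
        descriptors += [FeatureDescriptor(source, g) for g in mat.columns]

    onehot = pd.get_dummies(dataset.lineage).astype(float)
    blocks.append(onehot)
    descriptors += [FeatureDescriptor("lineage", str(c)) for c in onehot.columns]

    values = pd.concat(blocks, axis=1)
    values.columns = [d.key for d in descriptors]
    return FeatureTable(values, descriptors, target_gene)


def prune_features(table: FeatureTable, config: PreprocessConfig | None = None) -> FeatureTable:
    """Remove uninformative columns; the three rules are column-local.

    Drops constant columns (any source), indicator columns with
    <= min_category_support positive cells, and expression columns whose gene
    never reaches tpm_threshold TPM in any cell line.
    """
    config = config or PreprocessConfig()
    if table.normalization_state != "raw":
        raise ValueError("prune_features expects a raw (un-normalized) table")
    vals = table.values
    log_thresh = np.log2(config.tpm_threshold + 1.0)
    keep: list[FeatureDescriptor] = []
    arr = vals.to_numpy()
    for j, d in enumerate(table.descriptors):
        col = arr[:, j]
        if col.max() == col.min():
            continue
        if d.source in INDICATOR_SOURCES and (col > 0).sum() <= config.min_category_support:
            continue
        if d.source == "RNAseq" and col.max() < log_thresh:
            continue
        keep.append(d)
    return table.subset(keep)


def normalize(table: FeatureTable, statistics_from: Iterable[str] | None = None) -> FeatureTable:
    """Z-score expression and copy-number columns.

    Means and SDs come from ``statistics_from`` (typically the training
    cells) and are applied to every row, so held-out cells never influence
    the scaling. CERES, mutation and lineage columns pass through untouched.
    """
    if table.normalization_state == "zscored":
        raise ValueError("table is already z-scored")
    cells = list(statistics_from) if statistics_from is not None else list(table.values.index)
    if len(cells) == 0:
        raise ValueError("statistics_from is empty")
    vals = table.values.copy()
    cols = [d.key for d in table.descriptors if d.source in ("RNAseq", "CNV")]
    if cols:
        ref = vals.loc[cells, cols]
        mean = ref.mean(axis=0)
        sd = ref.std(axis=0, ddof=1)
        zero = sd.index[sd == 0]
        if len(zero):
            raise ValueError(f"zero-SD column(s) reached normalize: {list(zero)[:5]}"
                             " (should have been pruned)")
        vals[cols] = (vals[cols] - mean) / sd
    return FeatureTable(vals, list(table.descriptors), table.target_gene, "zscored")


def select_context_specific(ceres: pd.DataFrame,
                            config: PreprocessConfig | None = None) -> list[str]:
    """Genes with highly variable knockout phenotypes across cell lines.

    Keeps genes with sample SD (n-1 denominator) above ``sd_threshold`` and
    max-minus-min range above ``range_threshold``, in the matrix's gene order.
    """
    config = config or PreprocessConfig()
    sd = ceres.std(axis=0, ddof=1)
    rng = ceres.max(axis=0) - ceres.min(axis=0)
    mask = (sd > config.sd_threshold) & (rng > config.range_threshold)
    return [g for g in ceres.columns if mask[g]]


def correlation_vs_variability(ceres: pd.DataFrame, n_permutations: int = 163,
                               seed: int = 0) -> dict:
    """Regress each gene's best CERES correlation on its variability.

    For every gene: SD across cell lines, and the maximum pairwise Pearson
    correlation to any other gene. An OLS fit of max-correlation ~ SD gives
    the slope and its two-sided t-test p-value. Each permutation independently
    shuffles every gene's scores across cell lines and refits, yielding a
    null distribution of slope p-values.
    """
    if ceres.shape[1] < 3:
        raise ValueError("need at least 3 genes")
    if n_permutations < 0:
        raise ValueError("n_permutations must be >= 0")

    def _stat(mat: np.ndarray) -> tuple[float, float]:
        sd = mat.std(axis=0, ddof=1)
        corr = np.corrcoef(mat, rowvar=False)
        np.fill_diagonal(corr, -np.inf)
        maxcorr = corr.max(axis=0)
        res = stats.linregress(sd, maxcorr)
        return float(res.slope), float(res.pvalue)

    arr = ceres.to_numpy(dtype=float)
    slope, slope_p = _stat(arr)
    rng = np.random.default_rng(seed)
    perm_p = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_p[i] = _stat(rng.permuted(arr, axis=0))[1]
    return {"slope": slope, "slope_p": slope_p, "permutation_p_values": perm_p}
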