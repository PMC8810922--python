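"""DepMap-dialect table I/O and the aligned multi-omic container.

The Broad DepMap portal ships per-release CSVs: a gene-effect (CERES) matrix,
log2(TPM+1) expression, gene-level relative copy number, a long-format mutation
call table, and a sample-info table carrying lineage annotations. Matrices are
keyed by DepMap cell-line IDs in the row index and by ``"SYMBOL (entrezid)"``
column headers. This module reads and writes that dialect and assembles the
aligned :class:`MultiOmicDataset` everything downstream consumes.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MUTATION_CLASSES = ("damaging", "hotspot_nondamaging", "other")

#: canonical variant-annotation strings emitted per mutation class
_CLASS_TO_ANNOTATION = {
    "damaging": "damaging",
    "hotspot_nondamaging": "hotspot nondamaging",
    "other": "other conserving",
}

_GENE_HEADER_RE = re.compile(r"^(?P<symbol>.+?)\s*\((?P<entrez>[0-9&.]+)\)$")


@dataclass
class MultiOmicDataset:
    """Aligned per-cell-line matrices for one DepMap-style release.

    ``ceres`` holds gene-effect scores scaled so that the median common
    essential gene sits near -1 and nonessential genes near 0. ``expression``
    is on the TPM scale (the on-disk dialect is log2(TPM+1); the loader
    converts). ``mutations`` maps each of the three annotation classes to a
    cell x gene 0/1 indicator matrix.
    """

    ceres: pd.DataFrame
    expression: pd.DataFrame
    copy_number: pd.DataFrame
    mutations: dict[str, pd.DataFrame]
    lineage: pd.Series
    embedding2d: pd.DataFrame | None = None
    release_tag: str = "synthetic"
    entrez: dict[str, int] = field(default_factory=dict)

    @property
    def cells(self) -> pd.Index:
        return self.ceres.index

    @property
    def genes(self) -> pd.Index:
        return self.ceres.columns

    def validate(self) -> None:
        cells = self.ceres.index
        for name, df in [("expression", self.expression), ("copy_number", self.copy_number)]:
            if not df.index.equals(cells):
                raise ValueError(f"{name} is not aligned to the CERES cell-line index")
        for cls, mat in self.mutations.items():
            if not mat.index.equals(cells):
                raise ValueError(f"mutation matrix {cls!r} is not aligned")
            vals = mat.to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"mutation matrix {cls!r} has non-indicator values")
        if not self.lineage.index.equals(cells):
            raise ValueError("lineage is not aligned")
        if self.ceres.isna().any().any():
            raise ValueError("CERES matrix contains missing values after cleaning")


def _format_gene_columns(columns: pd.Index, entrez: dict[str, int]) -> list[str]:
    return [f"{g} ({entrez.get(g, 0)})" for g in columns]


def _parse_gene_columns(columns: list[str]) -> tuple[list[str], dict[str, int]]:
    symbols, entrez = [], {}
    for col in columns:
        m = _GENE_HEADER_RE.match(col.strip())
        if m is None:
            raise ValueError(f"malformed gene column header: {col!r}")
        sym = m.group("symbol")
        symbols.append(sym)
        try:
            entrez[sym] = int(m.group("entrez"))
        except ValueError:
            entrez[sym] = 0
    if len(set(symbols)) != len(symbols):
        raise ValueError("duplicated gene symbols in column headers")
    return symbols, entrez


def classify_annotation(annotation: str) -> str:
    """Route one variant-annotation string to its mutation class.

    Calls labelled damaging form the ``damaging`` class; non-damaging
    COSMIC/TCGA hotspot calls form ``hotspot_nondamaging``; other
    conserving/non-conserving calls form ``other``. Unrecognized strings are
    reported and routed to ``other``.
    """
    t = str(annotation).strip().lower()
    if "hotspot" in t:
        return "hotspot_nondamaging"
    if "damaging" in t and "nondamaging" not in t and "non-damaging" not in t:
        return "damaging"
    if "conserving" in t or "other" in t:
        return "other"
    warnings.warn(f"unrecognized variant annotation {annotation!r}; routed to 'other'")
    return "other"


def group_mutations(
    variant_table: pd.DataFrame,
    cells: pd.Index | None = None,
    genes: pd.Index | None = None,
) -> dict[str, pd.DataFrame]:
    """Collapse a long-format mutation call table into three indicator matrices.

    Each call lands in exactly one class; a gene-cell pair with calls of
    several classes sets each applicable indicator (indicators are
    class-specific evidence, not exclusive states).
    """
    table = variant_table.copy()
    if cells is None:
        cells = pd.Index(sorted(table["DepMap_ID"].unique()) if len(table) else [])
    if genes is None:
        genes = pd.Index(sorted(table["Hugo_Symbol"].unique()) if len(table) else [])
    out = {
        cls: pd.DataFrame(0, index=cells, columns=genes, dtype=np.int8)
        for cls in MUTATION_CLASSES
    }
    if len(table) == 0:
        return out
    table["_class"] = table["Variant_annotation"].map(classify_annotation)
    for cls, sub in table.groupby("_class"):
        sub = sub[sub["DepMap_ID"].isin(cells) & sub["Hugo_Symbol"].isin(genes)]
        if len(sub):
            ind = pd.crosstab(sub["DepMap_ID"], sub["Hugo_Symbol"]).clip(upper=1)
            out[cls] = out[cls].add(ind.reindex(index=cells, columns=genes, fill_value=0),
                                    fill_value=0).clip(upper=1).astype(np.int8)
    return out


def write_depmap_tables(dataset: MultiOmicDataset, directory: str | Path) -> dict:
    """Write the dataset as DepMap-dialect CSVs plus a JSON manifest.

    Expression is written as log2(TPM+1), matching the portal's file format.
    Returns the manifest (also stored as ``manifest.json`` in the directory).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entrez = dataset.entrez

    def _write_matrix(df: pd.DataFrame, fname: str) -> str:
        out = df.copy()
        out.columns = _format_gene_columns(df.columns, entrez)
        out.index.name = "DepMap_ID"
        out.to_csv(directory / fname)
        return fname

    manifest: dict = {"release_tag": dataset.release_tag}
    manifest["gene_effect"] = _write_matrix(dataset.ceres, "gene_effect.csv")
    logtpm = np.log2(dataset.expression + 1.0)
    manifest["expression"] = _write_matrix(logtpm, "expression.csv")
    manifest["copy_number"] = _write_matrix(dataset.copy_number, "copy_number.csv")

    rows = []
    for cls, mat in dataset.mutations.items():
        ann = _CLASS_TO_ANNOTATION[cls]
        cell_idx, gene_idx = np.nonzero(mat.to_numpy())
        for ci, gi in zip(cell_idx, gene_idx):
            gene = mat.columns[gi]
            rows.append((mat.index[ci], gene, entrez.get(gene, 0), ann))
    mut = pd.DataFrame(rows, columns=["DepMap_ID", "Hugo_Symbol", "Entrez_Gene_Id",
                                      "Variant_annotation"])
    mut.sort_values(["DepMap_ID", "Hugo_Symbol", "Variant_annotation"], inplace=True)
    mut.to_csv(directory / "mutations.csv", index=False)
    manifest["mutations"] = "mutations.csv"

    info = pd.DataFrame({"DepMap_ID": dataset.lineage.index, "lineage": dataset.lineage.values})
    info.to_csv(directory / "sample_info.csv", index=False)
    manifest["sample_info"] = "sample_info.csv"

    if dataset.embedding2d is not None:
        emb = dataset.embedding2d.copy()
        emb.columns = ["umap_1", "umap_2"]
        emb.index.name = "DepMap_ID"
        emb.to_csv(directory / "embedding.csv")
        manifest["embedding"] = "embedding.csv"

    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _read_matrix(path: Path) -> tuple[pd.DataFrame, dict[str, int]]:
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicated cell-line IDs in {path.name}")
    symbols, entrez = _parse_gene_columns(list(df.columns))
    df.columns = symbols
    return df, entrez


def load_depmap(source: str | Path | dict) -> MultiOmicDataset:
    """Load a DepMap-dialect release directory (or manifest) into memory.

    Cleaning rules applied on load: cell lines with any missing CERES value
    are dropped everywhere; all tables are restricted/aligned to the CERES
    cell-line index; missing copy-number entries become 0; the expression
    table is converted from log2(TPM+1) back to TPM.
    """
    if isinstance(source, dict):
        manifest = source
        directory = Path(manifest.get("_directory", "."))
    else:
        source = Path(source)
        directory = source if source.is_dir() else source.parent
        manifest_path = source / "manifest.json" if source.is_dir() else source
        with open(manifest_path) as fh:
            manifest = json.load(fh)

    ceres, entrez = _read_matrix(directory / manifest["gene_effect"])
    ceres = ceres.loc[~ceres.isna().any(axis=1)]
    cells = ceres.index

    logtpm, e2 = _read_matrix(directory / manifest["expression"])
    entrez.update(e2)
    expression = (np.power(2.0, logtpm) - 1.0).reindex(cells)

    copy_number, e3 = _read_matrix(directory / manifest["copy_number"])
    entrez.update(e3)
    copy_number = copy_number.reindex(cells).fillna(0.0)

    mut_table = pd.read_csv(directory / manifest["mutations"])
    mutations = group_mutations(mut_table, cells=cells, genes=ceres.columns)

    info = pd.read_csv(directory / manifest["sample_info"])
    lineage = info.set_index("DepMap_ID")["lineage"].reindex(cells)

    embedding = None
    if manifest.get("embedding"):
        emb = pd.read_csv(directory / manifest["embedding"], index_col=0)
        embedding = emb.reindex(cells)

    ds = MultiOmicDataset(
        ceres=ceres,
        expression=expression,
        copy_number=copy_number,
        mutations=mutations,
        lineage=lineage,
        embedding2d=embedding,
        release_tag=manifest.get("release_tag", "unknown"),
        entrez=entrez,
    )
    ds.validate()
    return ds
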