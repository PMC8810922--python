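"""Loading rules, mutation grouping, pruning, normalization, and the
context-specific target filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import depcompress as dc
from depcompress.datasets import group_mutations, load_depmap, write_depmap_tables
from depcompress.preprocess import (FeatureDescriptor, FeatureTable,
                                    PreprocessConfig, assemble_features,
                                    correlation_vs_variability, normalize,
                                    prune_features, select_context_specific)


# --- loader cleaning rules -------------------------------------------------

def test_cell_with_missing_ceres_is_dropped_everywhere(small_dataset, tmp_path):
    ds, _ = small_dataset
    write_depmap_tables(ds, tmp_path)
    path = tmp_path / "gene_effect.csv"
    lines = path.read_text().splitlines()
    cells = [ln.split(",")[0] for ln in lines[1:]]
    victim = cells[3]
    parts = lines[4].split(",")
    parts[5] = ""  # blank one CERES entry
    lines[4] = ",".join(parts)
    path.write_text("\n".join(lines) + "\n")
    back = load_depmap(tmp_path)
    assert victim not in back.ceres.index
    assert victim not in back.expression.index
    assert victim not in back.lineage.index


def test_missing_copy_number_loads_as_zero(small_dataset, tmp_path):
    ds, _ = small_dataset
    write_depmap_tables(ds, tmp_path)
    path = tmp_path / "copy_number.csv"
    lines = path.read_text().splitlines()
    parts = lines[1].split(",")
    cell, parts[2] = parts[0], ""
    lines[1] = ",".join(parts)
    path.write_text("\n".join(lines) + "\n")
    back = load_depmap(tmp_path)
    assert back.copy_number.loc[cell].iloc[1] == 0.0


# --- mutation grouping -----------------------------------------------------

@pytest.mark.parametrize("annotation,cls", [
    ("damaging", "damaging"),
    ("other conserving", "other"),
    ("other non-conserving", "other"),
    ("hotspot nondamaging", "hotspot_nondamaging"),
])
def test_annotation_routing(annotation, cls):
    table = pd.DataFrame({"DepMap_ID": ["ACH-1"], "Hugo_Symbol": ["TP53"],
                          "Variant_annotation": [annotation]})
    mats = group_mutations(table)
    assert mats[cls].loc["ACH-1", "TP53"] == 1
    for other_cls in set(mats) - {cls}:
        assert mats[other_cls].loc["ACH-1", "TP53"] == 0


def test_unrecognized_annotation_warns_and_routes_to_other():
    table = pd.DataFrame({"DepMap_ID": ["ACH-1"], "Hugo_Symbol": ["KRAS"],
                          "Variant_annotation": ["frameshift??"]})
    with pytest.warns(UserWarning):
        mats = group_mutations(table)
    assert mats["other"].loc["ACH-1", "KRAS"] == 1


def test_multiple_calls_set_multiple_class_indicators():
    table = pd.DataFrame({
        "DepMap_ID": ["ACH-1", "ACH-1"], "Hugo_Symbol": ["KRAS", "KRAS"],
        "Variant_annotation": ["damaging", "hotspot nondamaging"]})
    mats = group_mutations(table)
    assert mats["damaging"].loc["ACH-1", "KRAS"] == 1
    assert mats["hotspot_nondamaging"].loc["ACH-1", "KRAS"] == 1


def test_empty_call_table_gives_all_zero_matrices():
    cells, genes = pd.Index(["ACH-1", "ACH-2"]), pd.Index(["A", "B"])
    mats = group_mutations(pd.DataFrame(columns=["DepMap_ID", "Hugo_Symbol",
                                                 "Variant_annotation"]),
                           cells=cells, genes=genes)
    for m in mats.values():
        assert m.shape == (2, 2) and (m.to_numpy() == 0).all()


# --- pruning ---------------------------------------------------------------

def _toy_table():
    n = 30
    rng = np.random.default_rng(0)
    cols = {
        "CERES:VAR": rng.standard_normal(n),
        "CERES:CONST": np.full(n, -1.0),
        "RNAseq:LOW": np.log2(1 + np.full(n, 0.5)),   # max TPM 0.5 -> drop
        "RNAseq:HIGH": np.log2(1 + rng.uniform(2, 50, n)),
        "lineage:ten": np.r_[np.ones(10), np.zeros(n - 10)],     # exactly 10 -> drop
        "lineage:eleven": np.r_[np.ones(11), np.zeros(n - 11)],  # 11 -> keep
        "mutation_damaging:RARE": np.r_[np.ones(2), np.zeros(n - 2)],
    }
    descs = [FeatureDescriptor(*k.split(":")) for k in cols]
    return FeatureTable(pd.DataFrame(cols), descs, "TARGET")


def test_pruning_rules():
    pruned = prune_features(_toy_table(), PreprocessConfig())
    kept = {d.key for d in pruned.descriptors}
    assert kept == {"CERES:VAR", "RNAseq:HIGH", "lineage:eleven"}


def test_pruning_is_idempotent_and_cell_order_invariant():
    table = _toy_table()
    once = prune_features(table)
    twice = prune_features(once)
    assert [d.key for d in once.descriptors] == [d.key for d in twice.descriptors]
    shuffled = FeatureTable(table.values.sample(frac=1, random_state=1),
                            list(table.descriptors), table.target_gene)
    assert {d.key for d in prune_features(shuffled).descriptors} == \
        {d.key for d in once.descriptors}


# --- normalization ---------------------------------------------------------

def test_normalize_scales_only_continuous_omics():
    table = prune_features(_toy_table())
    stats_cells = list(table.values.index[:20])
    normed = normalize(table, stats_cells)
    rna = normed.values.loc[stats_cells, "RNAseq:HIGH"]
    assert abs(rna.mean()) < 1e-9 and abs(rna.std(ddof=1) - 1) < 1e-9
    assert (normed.values["CERES:VAR"] == table.values["CERES:VAR"]).all()
    assert (normed.values["lineage:eleven"] == table.values["lineage:eleven"]).all()
    assert normed.normalization_state == "zscored"
    with pytest.raises(ValueError):
        normalize(normed, stats_cells)  # double scoring rejected


def test_normalize_zero_sd_column_is_an_error():
    descs = [FeatureDescriptor("RNAseq", "X")]
    table = FeatureTable(pd.DataFrame({"RNAseq:X": np.ones(5)}), descs, "T")
    with pytest.raises(ValueError, match="RNAseq:X"):
        normalize(table)


# --- feature assembly ------------------------------------------------------

def test_assemble_features_contracts(small_dataset):
    ds, _ = small_dataset
    target = ds.ceres.columns[7]
    table = assemble_features(ds, target)
    keys = {d.key for d in table.descriptors}
    assert f"CERES:{target}" not in keys        # own knockout excluded
    assert f"RNAseq:{target}" in keys           # own expression retained (dosage)
    census = table.census()
    assert len(table.descriptors) == sum(census.values())
    assert census["CERES"] == ds.ceres.shape[1] - 1
    with pytest.raises(KeyError):
        assemble_features(ds, "NOT_A_GENE")


# --- context-specific target selection -------------------------------------

def test_select_context_specific_hand_examples():
    mat = pd.DataFrame({"in": [-1.0, -0.2, -0.9], "out": [-0.1, 0.1, 0.0]})
    assert select_context_specific(mat) == ["in"]
    assert np.isclose(mat["in"].std(ddof=1), 0.43589, atol=1e-4)
    const = pd.DataFrame({"c": [0.5, 0.5, 0.5]})
    assert select_context_specific(const) == []


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.0, 0.5), st.floats(0.0, 1.0))
def test_select_context_specific_monotone_in_thresholds(seed, d_sd, d_range):
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(rng.normal(0, 0.4, size=(12, 8)),
                       columns=[f"g{i}" for i in range(8)])
    base = set(select_context_specific(mat, PreprocessConfig()))
    tighter = PreprocessConfig(sd_threshold=0.25 + d_sd,
                               range_threshold=0.6 + d_range)
    assert set(select_context_specific(mat, tighter)) <= base
    shuffled = mat.sample(frac=1, random_state=1)
    assert select_context_specific(shuffled) == select_context_specific(mat)


# --- correlation vs variability -------------------------------------------

def test_correlation_vs_variability_detects_planted_structure(low_noise_dataset):
    """Structured data: tiny slope p; permuted data: p values far larger."""
    ds, truth = low_noise_dataset
    genes = list(ds.ceres.columns[:80])
    res = correlation_vs_variability(ds.ceres[genes], n_permutations=20, seed=0)
    assert res["slope"] > 0
    assert res["slope_p"] < 1e-10
    assert (res["permutation_p_values"] > res["slope_p"]).all()


def test_correlation_vs_variability_input_contracts():
    mat = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 2)))
    with pytest.raises(ValueError):
        correlation_vs_variability(mat, 5, 0)
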