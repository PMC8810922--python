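"""Generator contracts: planted structure, class scaling, reproducibility,
and the DepMap-dialect round trip."""

import numpy as np
import pandas as pd
import pytest

import depcompress as dc
from depcompress import (GeneratorConfig, generate_dataset, load_depmap,
                         select_context_specific, write_depmap_tables)


def test_generation_is_bit_reproducible(small_config):
    a, _ = generate_dataset(small_config)
    b, _ = generate_dataset(small_config)
    assert (a.ceres.to_numpy() == b.ceres.to_numpy()).all()
    assert (a.expression.to_numpy() == b.expression.to_numpy()).all()
    for cls in a.mutations:
        assert (a.mutations[cls].to_numpy() == b.mutations[cls].to_numpy()).all()


def test_different_seed_changes_data(small_config):
    import dataclasses
    a, _ = generate_dataset(small_config)
    b, _ = generate_dataset(dataclasses.replace(small_config, seed=99))
    assert not np.allclose(a.ceres.to_numpy(), b.ceres.to_numpy())


def test_noise_free_selective_genes_are_exact_factor_readouts(noise_free_dataset):
    """With zero noise, same-factor genes correlate at exactly +/-1."""
    ds, truth = noise_free_dataset
    by_factor = {}
    for g, k in truth.cluster_assignment.items():
        by_factor.setdefault(k, []).append(g)
    checked = 0
    for k, members in by_factor.items():
        if len(members) < 2:
            continue
        corr = np.corrcoef(ds.ceres[members].to_numpy(), rowvar=False)
        assert np.allclose(np.abs(corr), 1.0, atol=1e-9)
        checked += 1
    assert checked > 0


def test_class_means_recovered(noise_free_dataset, small_dataset):
    ds0, truth0 = noise_free_dataset
    ce = truth0.genes_of_class("common_essential")
    ne = truth0.genes_of_class("nonessential")
    assert np.allclose(ds0.ceres[ce].to_numpy(), -1.0)
    assert np.allclose(ds0.ceres[ne].to_numpy(), 0.0)
    ds, truth = small_dataset
    tol = 3 * 0.15 / np.sqrt(ds.ceres.shape[0])
    assert abs(ds.ceres[truth.genes_of_class("common_essential")].to_numpy().mean()
               + 1.0) < tol * 3
    assert abs(ds.ceres[truth.genes_of_class("nonessential")].to_numpy().mean()) < tol * 3


def test_no_selective_fraction_yields_no_context_specific_genes():
    cfg = GeneratorConfig(n_cells=60, n_genes=100, n_factors=1,
                          class_fractions=(0.3, 0.0, 0.7), noise_sd=0.05,
                          n_synthetic_lethal=0, n_dosage=0, n_paralog_pairs=0,
                          n_lineage_effects=0, seed=3)
    ds, _ = generate_dataset(cfg)
    assert select_context_specific(ds.ceres) == []


def test_default_config_selective_genes_pass_variability_filter():
    """>=90% of planted selective genes clear the SD>0.25 & range>0.6 filter.

    Oracle: the planted loadings and factor variance imply SD well above the
    cutoff for every selective gene; verified empirically on the realization.
    """
    ds, truth = generate_dataset(GeneratorConfig())
    chosen = set(select_context_specific(ds.ceres))
    selective = truth.genes_of_class("selective")
    frac = np.mean([g in chosen for g in selective])
    assert frac >= 0.9


def test_planted_predictors_recoverable_by_univariate_scan(low_noise_dataset):
    """Brute-force oracle: every planted predictor's feature column correlates
    with its target more strongly than ~all random columns."""
    ds, truth = low_noise_dataset
    logtpm = np.log2(ds.expression + 1.0)
    onehot = pd.get_dummies(ds.lineage).astype(float)
    source_mat = {
        "CERES": ds.ceres, "RNAseq": logtpm,
        "mutation_damaging": ds.mutations["damaging"].astype(float),
        "lineage": onehot,
    }
    rng = np.random.default_rng(0)
    for target, preds in truth.planted_predictors.items():
        y = ds.ceres[target].to_numpy()
        for desc, relation in preds:
            col = source_mat[desc.source][desc.name].to_numpy()
            r_planted = abs(np.corrcoef(col, y)[0, 1])
            # compare to a background of random CERES columns
            bg = [abs(np.corrcoef(ds.ceres[g].to_numpy(), y)[0, 1])
                  for g in rng.choice(ds.ceres.columns, size=30, replace=False)
                  if g != target and g != desc.name]
            assert r_planted > 0.25, (target, desc, relation, r_planted)
            assert r_planted > np.median(bg)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(class_fractions=(0.5, 0.2, 0.2)).validate()
    with pytest.raises(ValueError):
        GeneratorConfig(n_genes=30, n_factors=2).validate()  # too few selective genes
    with pytest.raises(ValueError):
        GeneratorConfig(n_cells=-1).validate()


def test_depmap_round_trip(small_dataset, tmp_path):
    """write -> load preserves matrices to 1e-9 and labels exactly."""
    ds, _ = small_dataset
    manifest = write_depmap_tables(ds, tmp_path)
    assert set(manifest) >= {"gene_effect", "expression", "copy_number",
                             "mutations", "sample_info"}
    back = load_depmap(tmp_path)
    for name in ("ceres", "expression", "copy_number"):
        a, b = getattr(ds, name), getattr(back, name)
        assert list(a.columns) == list(b.columns)
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 1e-9
    for cls in ds.mutations:
        assert (ds.mutations[cls].to_numpy() == back.mutations[cls].to_numpy()).all()
    assert (ds.lineage == back.lineage).all()
    assert np.abs(ds.embedding2d.to_numpy() - back.embedding2d.to_numpy()).max() < 1e-9


def test_gene_headers_follow_symbol_entrez_dialect(small_dataset, tmp_path):
    ds, _ = small_dataset
    write_depmap_tables(ds, tmp_path)
    header = (tmp_path / "gene_effect.csv").read_text().splitlines()[0]
    first = header.split(",")[1]
    sym, ent = first.split(" (")
    assert sym == ds.ceres.columns[0]
    assert int(ent.rstrip(")")) == ds.entrez[sym]


def test_zero_mutation_dataset_round_trips_as_all_zero_indicators(
        small_dataset, tmp_path):
    import dataclasses
    ds, _ = small_dataset
    empty = dataclasses.replace(
        ds, mutations={cls: m * 0 for cls, m in ds.mutations.items()})
    write_depmap_tables(empty, tmp_path)
    assert len((tmp_path / "mutations.csv").read_text().strip().splitlines()) == 1
    back = load_depmap(tmp_path)
    for cls in back.mutations:
        assert (back.mutations[cls].to_numpy() == 0).all()
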