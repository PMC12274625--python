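"""Generator contracts: determinism, planted-truth bookkeeping, file round-trips."""

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from radnet import io
from radnet.simulate import (SimulationConfig, generate_annotations,
                             generate_expression, generate_interactome,
                             ground_truth)


def test_identical_config_gives_identical_outputs():
    cfg = SimulationConfig(n_genes=100, n_mirnas=10, n_tfs=5, rng_seed=1)
    e1, _ = generate_expression(cfg)
    e2, _ = generate_expression(cfg)
    pdt.assert_frame_equal(e1.values, e2.values)
    t1 = generate_interactome(cfg)
    t2 = generate_interactome(cfg)
    for layer in t1:
        pdt.assert_frame_equal(t1[layer], t2[layer])
    a1 = generate_annotations(cfg)
    a2 = generate_annotations(cfg)
    assert a1[0] == a2[0]
    pdt.assert_frame_equal(a1[3], a2[3])


def test_no_planted_effect_means_empty_truth():
    cfg = SimulationConfig(n_genes=100, n_mirnas=10, n_tfs=5,
                           effect_lfc=0.0, frac_true_de=0.0, rng_seed=2)
    _, gt = generate_expression(cfg)
    assert gt.true_de_features == {}


def test_true_de_count_follows_rounding_rule():
    cfg = SimulationConfig(n_genes=1000, n_mirnas=100, n_tfs=50,
                           frac_true_de=0.1, rng_seed=3)
    _, gt = generate_expression(cfg)
    assert len(gt.true_de_features) == round(0.1 * 1150)
    # planted magnitudes are exactly +-effect_lfc
    assert set(np.abs(list(gt.true_de_features.values()))) == {cfg.effect_lfc}


def test_paired_design_and_planted_mean_difference():
    cfg = SimulationConfig(n_genes=400, n_mirnas=40, n_tfs=20,
                           frac_true_de=0.2, noise_sd=0.3, rng_seed=4)
    expr, gt = generate_expression(cfg)
    assert expr.values.shape[1] == 2 * cfg.n_donors
    assert set(expr.sample_meta.condition) == {"control", "irradiated"}
    meta = expr.sample_meta
    irr = meta[meta.condition == "irradiated"].sample_id.tolist()
    ctl = meta[meta.condition == "control"].sample_id.tolist()
    diffs = expr.values[irr].to_numpy() - expr.values[ctl].to_numpy()
    planted = np.array([f in gt.true_de_features for f in expr.values.index])
    lfc = np.array([gt.true_de_features.get(f, 0.0) for f in expr.values.index])
    # observed mean difference concentrates on the planted value
    err = diffs.mean(axis=1) - lfc
    assert np.abs(err[planted]).mean() < 0.5
    assert np.abs(diffs.mean(axis=1)[~planted]).mean() < 0.5


def test_single_donor_rejected():
    cfg = SimulationConfig(n_genes=20, n_mirnas=5, n_tfs=2, n_donors=1)
    with pytest.raises(ValueError, match="donor"):
        generate_expression(cfg)


@pytest.mark.parametrize("bad", [
    dict(n_genes=0), dict(frac_true_de=1.5), dict(confidence_range=(0.5, 1.2)),
    dict(planted_module_sizes=(50,), n_genes=20, n_mirnas=5, n_tfs=2),
])
def test_invalid_configs_rejected(bad):
    cfg = SimulationConfig(**{**dict(n_genes=30, n_mirnas=5, n_tfs=3), **bad})
    with pytest.raises(ValueError):
        cfg.validate()


def test_planted_clique_edges_present_in_ppi():
    cfg = SimulationConfig(n_genes=200, n_mirnas=20, n_tfs=10,
                           planted_module_sizes=(5,), rng_seed=6)
    tables = generate_interactome(cfg)
    gt = ground_truth(cfg)
    (clique,) = gt.planted_modules
    ppi_pairs = {frozenset(p) for p in
                 zip(tables["ppi"].source, tables["ppi"].target)}
    members = sorted(clique)
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            assert frozenset((members[i], members[j])) in ppi_pairs


def test_ppi_confidence_within_range():
    cfg = SimulationConfig(n_genes=150, n_mirnas=15, n_tfs=8,
                           confidence_range=(0.8, 1.0), rng_seed=7)
    conf = generate_interactome(cfg)["ppi"]["confidence"]
    assert conf.min() >= 0.8 and conf.max() <= 1.0


def test_edge_count_matches_density_budget():
    cfg = SimulationConfig(n_genes=400, n_mirnas=60, n_tfs=40,
                           interactome_density=3.0, rng_seed=8)
    tables = generate_interactome(cfg)
    all_rows = pd.concat(tables.values())
    valid = all_rows[all_rows.source != all_rows.target]
    pairs = {frozenset(p) for p in zip(valid.source, valid.target)}
    expected = 3.0 * 500
    assert abs(len(pairs) - expected) <= 3 * np.sqrt(expected) + \
        sum(s * (s - 1) / 2 for s in cfg.planted_module_sizes)


def test_interactome_contains_deliberate_dirt():
    cfg = SimulationConfig(n_genes=100, n_mirnas=10, n_tfs=5, rng_seed=9)
    ppi = generate_interactome(cfg)["ppi"]
    assert (ppi.source == ppi.target).any(), "missing injected self-loop"
    assert ppi.duplicated(["source", "target"]).any(), "missing injected duplicate"


def test_annotation_structure(small_config, small_world):
    _, _, gene_sets, assoc, cat_map, profiles, gt = small_world
    # every disease has exactly one category
    assert set(assoc.disease_id) <= set(cat_map.disease_id)
    assert not cat_map.disease_id.duplicated().any()
    assert cat_map.category_id.nunique() <= small_config.n_categories
    # exactly the configured number of reversal compounds
    assert len(gt.reversal_compounds) == small_config.n_reversal_compounds
    # each profile is a permutation of 1..n_ref
    for _, grp in profiles.groupby("compound_id"):
        assert sorted(grp["rank"]) == list(range(1, len(grp) + 1))


def test_planted_sets_are_stacked_with_true_de(small_world):
    _, _, gene_sets, _, _, _, gt = small_world
    de = set(gt.true_de_features)
    universe = {m for s in gene_sets.values() for m in s}
    base_rate = len(de & universe) / len(universe)
    for name in gt.enriched_sets:
        share = len(gene_sets[name] & de) / len(gene_sets[name])
        assert share > 3 * base_rate, f"{name} not visibly enriched"


def test_round_trips(tmp_path, small_world):
    expr, tables, gene_sets, assoc, cat_map, profiles, _ = small_world
    io.write_expression(expr, tmp_path / "e.tsv", tmp_path / "m.tsv",
                        tmp_path / "f.tsv")
    back = io.read_expression(tmp_path / "e.tsv", tmp_path / "m.tsv",
                              tmp_path / "f.tsv")
    pdt.assert_frame_equal(back.values, expr.values)
    pdt.assert_frame_equal(back.sample_meta, expr.sample_meta)

    io.write_edge_table(tables["ppi"], tmp_path / "ppi.tsv")
    ppi = io.read_edge_table(tmp_path / "ppi.tsv")
    pdt.assert_frame_equal(ppi, tables["ppi"].reset_index(drop=True),
                           check_exact=False)

    io.write_gmt(gene_sets, tmp_path / "sets.gmt")
    assert io.read_gmt(tmp_path / "sets.gmt") == gene_sets

    io.write_table(profiles, tmp_path / "p.tsv")
    pdt.assert_frame_equal(io.read_table(tmp_path / "p.tsv"), profiles)
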