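"""Differential expression: probe collapse, moderated t, BH, calling rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radnet import diffexpr
from radnet.simulate import PairedExpressionSet, SimulationConfig, generate_expression


def _paired_set(diff_matrix: np.ndarray, mirna_rows=()) -> PairedExpressionSet:
    """Controls at 0, irradiated equal to the given per-donor differences."""
    nf, nd = diff_matrix.shape
    features = [f"F{i}" for i in range(nf)]
    cols, data, meta = [], [], []
    for d in range(nd):
        cols += [f"d{d}_ctl", f"d{d}_irr"]
        meta += [(f"d{d}_ctl", f"d{d}", "control"),
                 (f"d{d}_irr", f"d{d}", "irradiated")]
        data += [np.zeros(nf), diff_matrix[:, d]]
    values = pd.DataFrame(np.column_stack(data),
                          index=pd.Index(features, name="feature_id"), columns=cols)
    fmeta = pd.DataFrame({"feature_id": features,
                          "molecule_type": ["miRNA" if i in mirna_rows else "gene"
                                            for i in range(nf)]})
    smeta = pd.DataFrame(meta, columns=["sample_id", "donor", "condition"])
    return PairedExpressionSet(values, fmeta, smeta)


# ---------------------------------------------------------------- collapse
@pytest.mark.parametrize("probes, expected", [
    ({"p1": [2.0], "p2": [4.0]}, 3.0),
    ({"p1": [1.0], "p2": [2.0], "p3": [6.0]}, 3.0),
])
def test_collapse_probes_takes_arithmetic_mean(probes, expected):
    mat = pd.DataFrame(probes).T
    mat.columns = ["s1"]
    out = diffexpr.collapse_probes(mat, {p: "geneA" for p in probes})
    assert out.loc["geneA", "s1"] == pytest.approx(expected)


def test_collapse_identity_and_unmapped_exclusion():
    mat = pd.DataFrame({"s1": [1.0, 2.0]}, index=["p1", "p2"])
    out = diffexpr.collapse_probes(mat, {"p1": "g1", "p2": "g2"})
    assert out.shape == (2, 1) and sorted(out.index) == ["g1", "g2"]
    out = diffexpr.collapse_probes(mat, {"p1": "g1"})
    assert list(out.index) == ["g1"]


# ---------------------------------------------------------------- moderated t
def test_unmoderated_t_matches_closed_form():
    diffs = np.vstack([[1, 2, 3, 4, 5], [0, 0, 1, -1, 0]]).astype(float)
    res = diffexpr.paired_moderated_t(_paired_set(diffs), d0_override=0)
    row = res.set_index("feature_id").loc["F0"]
    assert row.t_stat == pytest.approx(4.2426, abs=1e-4)
    assert row.df_total == 4
    assert row.p_raw == pytest.approx(0.0132, abs=2e-4)
    assert row.log2fc == pytest.approx(3.0)


def test_unmoderated_t_equals_scipy_paired_t():
    rng = np.random.default_rng(0)
    diffs = rng.normal(size=(50, 5))
    expr = _paired_set(diffs)
    res = diffexpr.paired_moderated_t(expr, d0_override=0)
    t_ref = stats.ttest_rel(diffs, np.zeros_like(diffs), axis=1)
    np.testing.assert_allclose(res.t_stat.to_numpy(), t_ref.statistic, atol=1e-12)
    np.testing.assert_allclose(res.p_raw.to_numpy(), t_ref.pvalue, atol=1e-12)


def test_constant_matrix_gives_zero_lfc():
    diffs = np.zeros((5, 4))
    diffs[0, :] = [1, -1, 1, -1]  # one varying feature keeps the prior identifiable
    res = diffexpr.paired_moderated_t(_paired_set(diffs))
    assert (res.log2fc.iloc[1:] == 0).all()


def test_all_zero_variance_is_an_error():
    diffs = np.ones((4, 5))  # every feature has identical differences
    with pytest.raises(ValueError, match="zero variance"):
        diffexpr.paired_moderated_t(_paired_set(diffs))


def test_infinite_prior_pools_all_variances():
    rng = np.random.default_rng(1)
    diffs = rng.normal(size=(30, 5))
    res = diffexpr.paired_moderated_t(_paired_set(diffs), d0_override=np.inf)
    assert np.isinf(res.df_total).all()
    # pooled: t proportional to lfc with one shared scale
    ratio = res.t_stat / res.log2fc
    np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-9)


def test_moderation_shrinks_toward_prior():
    cfg = SimulationConfig(n_genes=1500, n_mirnas=100, n_tfs=50,
                           frac_true_de=0.0, rng_seed=13)
    expr, _ = generate_expression(cfg)
    meta = expr.sample_meta
    donors = sorted(meta.donor.unique())
    irr = [meta[(meta.donor == d) & (meta.condition == "irradiated")].sample_id.item()
           for d in donors]
    ctl = [meta[(meta.donor == d) & (meta.condition == "control")].sample_id.item()
           for d in donors]
    s2 = (expr.values[irr].to_numpy() - expr.values[ctl].to_numpy()).var(1, ddof=1)
    d0, s0_2 = diffexpr.fit_variance_prior(s2, len(donors) - 1)
    # generator planted d0=4, s0^2=noise_sd^2=0.25
    assert d0 == pytest.approx(4.0, rel=0.5)
    assert s0_2 == pytest.approx(0.25, rel=0.25)


def test_monotone_in_effect_size_at_fixed_variance():
    base = np.array([-1.0, 1.0, 0.5, -0.5, 0.0])
    shifts = [0.0, 0.5, 1.0, 2.0, 4.0]
    diffs = np.vstack([base + s for s in shifts])
    res = diffexpr.paired_moderated_t(_paired_set(diffs))
    t_abs = res.t_stat.abs().to_numpy()
    assert np.all(np.diff(t_abs) >= -1e-12)


# ---------------------------------------------------------------- BH
def test_bh_adjust_step_up():
    assert diffexpr.bh_adjust([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(diffexpr.bh_adjust([1.0, 1.0]), [1.0, 1.0])
    with pytest.raises(ValueError):
        diffexpr.bh_adjust([0.5, 1.5])


def test_bh_dominates_raw_p():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=200)
    adj = diffexpr.bh_adjust(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)


# ---------------------------------------------------------------- calling
def _row(mt, lfc, p_raw, p_adj):
    return pd.DataFrame([{"feature_id": "x", "molecule_type": mt, "log2fc": lfc,
                          "t_stat": 0.0, "df_total": 8, "p_raw": p_raw,
                          "p_adj": p_adj}])


@pytest.mark.parametrize("mt, lfc, p_raw, p_adj, expected", [
    ("gene", 1.5, 0.001, 0.04, "up"),           # genes judged on adjusted p
    ("miRNA", -1.2, 0.04, 0.3, "down"),         # miRNAs judged on raw p
    ("gene", -1.2, 0.04, 0.3, "not_significant"),
    ("gene", 1.0, 0.001, 0.001, "not_significant"),  # |lfc| > 1 is strict
    ("gene", -3.0, 0.2, 0.9, "not_significant"),
])
def test_call_de_rules(mt, lfc, p_raw, p_adj, expected):
    out = diffexpr.call_de(_row(mt, lfc, p_raw, p_adj))
    assert out.status.iloc[0] == expected


def test_call_de_rejects_unknown_molecule_type():
    with pytest.raises(ValueError, match="unknown molecule_type"):
        diffexpr.call_de(_row("protein", 2.0, 0.01, 0.01))


def test_mirna_raw_p_rule_can_be_disabled():
    out = diffexpr.call_de(_row("miRNA", -1.2, 0.04, 0.3),
                           mirna_uses_raw_p=False)
    assert out.status.iloc[0] == "not_significant"


# ---------------------------------------------------------------- calibration
def test_null_type_one_rate_is_calibrated():
    cfg = SimulationConfig(n_genes=1800, n_mirnas=120, n_tfs=80,
                           frac_true_de=0.0, rng_seed=7)
    expr, _ = generate_expression(cfg)
    res = diffexpr.paired_moderated_t(expr)
    frac = (res.p_raw < 0.05).mean()
    sd = np.sqrt(0.05 * 0.95 / len(res))
    assert abs(frac - 0.05) < 3 * sd


def test_planted_effects_recovered():
    cfg = SimulationConfig(rng_seed=11)  # effect 2, noise_sd 0.5, 5 donors
    expr, gt = generate_expression(cfg)
    res = diffexpr.call_de(diffexpr.paired_moderated_t(expr))
    called = set(res.loc[res.status != "not_significant", "feature_id"])
    truth = set(gt.true_de_features)
    assert len(called & truth) / len(truth) >= 0.90
    assert len(called - truth) / max(len(called), 1) <= 0.10
    # signs agree with the planted direction
    status = res.set_index("feature_id").status
    for f in called & truth:
        assert (status[f] == "up") == (gt.true_de_features[f] > 0)
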