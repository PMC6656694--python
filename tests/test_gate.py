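import numpy as np
import pytest

import cytomon as cm
from cytomon import gate, simulate as sim
from cytomon.errors import ConfigurationError, ScaleError
from conftest import make_matrix


# ------------------------------------------------------------- transforms

def test_arcsinh_closed_form(pbmc_sample):
    m, _ = pbmc_sample
    t = gate.arcsinh_transform(m, cofactor=5)
    assert t.scale == "arcsinh"
    x = np.array([[0.0], [5.0], [50.0]])
    tm = gate.arcsinh_transform(make_matrix(x, scale="raw"))
    assert tm.values[0, 0] == 0.0
    assert tm.values[1, 0] == pytest.approx(np.log(1 + np.sqrt(2)), abs=1e-12)
    # strictly increasing
    assert np.all(np.diff(tm.values[:, 0]) > 0)


def test_arcsinh_requires_raw(pbmc_transformed):
    t, _ = pbmc_transformed
    with pytest.raises(ScaleError):
        gate.arcsinh_transform(t)


def test_percentile_normalize_constant_channel():
    m = make_matrix(np.full((200, 1), 3.0), scale="arcsinh")
    out = gate.percentile_normalize(m)
    assert np.allclose(out.values, 1.0)
    assert out.scale == "arcsinh_p995"


def test_percentile_normalize_tail_fraction():
    rng = np.random.default_rng(0)
    m = make_matrix(rng.uniform(0, 5, (200000, 1)), scale="arcsinh")
    out = gate.percentile_normalize(m, p=99.5)
    frac = (out.values > 1).mean()
    assert frac == pytest.approx(0.005, abs=0.001)


def test_percentile_normalize_zero_channel_warns():
    m = make_matrix(np.zeros((100, 1)), scale="arcsinh")
    with pytest.warns(UserWarning, match="unscaled"):
        out = gate.percentile_normalize(m)
    assert np.array_equal(out.values, m.values)


def test_percentile_normalize_requires_arcsinh(pbmc_sample):
    m, _ = pbmc_sample
    with pytest.raises(ScaleError):
        gate.percentile_normalize(m)
    with pytest.raises(ConfigurationError):
        gate.TransformSpec(percentile=150)


def test_pipeline_approximate_scale_equivariance(pbmc_sample):
    """A global 10% sensitivity change barely moves percentile-normalized
    intensities (arcsinh is log-like above its elbow, so the percentile
    divisor absorbs most of the factor) and never reorders events."""
    m, _ = pbmc_sample
    scaled = m.with_values(m.values * 1.1)
    a = gate.percentile_normalize(gate.arcsinh_transform(m))
    b = gate.percentile_normalize(gate.arcsinh_transform(scaled))
    assert np.quantile(np.abs(b.values - a.values), 0.99) < 0.05
    col = a.column_index(antigen="CD45")
    assert np.array_equal(np.argsort(a.values[:, col], kind="stable"),
                          np.argsort(b.values[:, col], kind="stable"))


# ---------------------------------------------------------------- cutoffs

def test_cutoff_table_invariants():
    with pytest.raises(ConfigurationError):
        gate.Cutoff(2.0, 1.0)
    ct = gate.CutoffTable({"A": gate.Cutoff(1.0, 2.0)})
    scaled = ct.rescale({"A": 2.0})
    assert scaled.primary("A") == 0.5 and scaled.secondary("A") == 1.0
    with pytest.raises(ConfigurationError):
        ct.primary("missing")


def test_estimate_cutoffs_balanced_mixture_valley():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(0.2, 0.1, 5000), rng.normal(0.8, 0.1, 5000)])
    m = make_matrix(np.clip(x, 0, None)[:, None], names=["A"], scale="arcsinh")
    ct = gate.estimate_cutoffs(m, ["A"], secondary=True)
    assert 0.4 <= ct.primary("A") <= 0.6
    assert ct.secondary("A") > ct.primary("A")


def test_estimate_cutoffs_stable_under_resampling():
    vals = []
    for seed in (3, 4):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0.2, 0.1, 5000),
                            rng.normal(0.8, 0.1, 5000)])
        m = make_matrix(x[:, None], names=["A"], scale="arcsinh")
        vals.append(gate.estimate_cutoffs(m, ["A"]).primary("A"))
    assert abs(vals[0] - vals[1]) < 0.05


def test_estimate_cutoffs_unimodal_fallback():
    rng = np.random.default_rng(1)
    x = rng.normal(1.0, 0.1, 5000)
    m = make_matrix(x[:, None], names=["A"], scale="arcsinh")
    ct = gate.estimate_cutoffs(m, ["A"])
    assert ct.primary("A") > 1.0  # above the single mode


def test_estimate_cutoffs_needs_events():
    m = make_matrix(np.zeros((50, 1)), scale="arcsinh")
    with pytest.raises(ValueError, match="insufficient"):
        gate.estimate_cutoffs(m, ["M0"])


# ----------------------------------------------------------------- pregate

def test_pregate_attrition_matches_generator(cutoffs):
    cfg = sim.profile_config("pbmc_default", 40000, seed=8)
    m, gt = sim.simulate_sample(cfg)
    t = gate.arcsinh_transform(m)
    keep, att = gate.pregate(t, cutoffs)
    report = att.set_index("stage")["fraction_kept"]
    n = m.n_events
    for stage, expected in [("non-beads", 0.95), ("singlets", 0.98),
                            ("live", 0.97)]:
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(report[stage] - expected) <= 4 * se + 0.003, stage
    # attrition telescopes
    assert keep.sum() == att["events_out"].iloc[-1]
    assert np.all(att["events_out"].to_numpy() <= att["events_in"].to_numpy())


def test_pregate_clean_input_passes_everything(cutoffs):
    cfg = sim.profile_config("pbmc_default", 5000, seed=2, bead_fraction=0.0,
                             dead_fraction=0.0, doublet_rate=0.0)
    m, _ = sim.simulate_sample(cfg)
    keep, att = gate.pregate(gate.arcsinh_transform(m), cutoffs)
    early = att.set_index("stage")["fraction_kept"]
    for stage in ("non-beads", "DNA+", "singlets", "live"):
        assert early[stage] >= 0.998, stage


def test_pregate_removes_erythrocytes(cutoffs, pbmc_lineages):
    templates = sim.templates_from_lineages(
        pbmc_lineages, {"Classical monocytes": 1.0},
        extras=sim.EXTRA_LOCATIONS)
    for tpl in templates:
        tpl.location["CD235ab"] = 4.0  # erythrocyte-like contamination
    m, _ = sim.simulate_sample(sim.SimConfig(n_events=2000, seed=0,
                                             templates=templates))
    keep, att = gate.pregate(gate.arcsinh_transform(m), cutoffs)
    row = att.set_index("stage").loc["CD235ab/CD61-"]
    assert row["fraction_kept"] < 0.01


def test_pregate_missing_channel_names_stage(cutoffs, pbmc_sample):
    m, _ = pbmc_sample
    t = gate.arcsinh_transform(m)
    broken = t.subset(np.ones(t.n_events, bool))
    broken.channel_meta.loc[
        broken.channel_meta["antigen"] == "Cisplatin", "antigen"] = "Gone"
    with pytest.raises(ConfigurationError, match="live"):
        gate.pregate(broken, cutoffs)


# ------------------------------------------------------------------ gating

def test_gating_recovers_population_frequencies(cutoffs, pbmc_lineages,
                                                pbmc_transformed):
    t, gt = pbmc_transformed
    keep, _ = gate.pregate(t, cutoffs)
    tree = gate.build_gating_tree(pbmc_lineages)
    res = gate.apply_gating(t, tree, cutoffs, mask=keep)
    assert res.assigned_to_leaf_fraction >= 0.984
    n = res.n_pregated
    for name in ("Treg", "Classical monocytes", "CD27- B cells"):
        p = gt.true_frequencies[name]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(res.frequency(name) - p) <= 4 * se + 0.002, name


def test_gating_counts_conserve(cutoffs, pbmc_lineages, pbmc_transformed):
    t, _ = pbmc_transformed
    keep, _ = gate.pregate(t, cutoffs)
    tree = gate.build_gating_tree(pbmc_lineages)
    res = gate.apply_gating(t, tree, cutoffs, mask=keep)

    def check(node):
        child_sum = sum(res.counts[c.name] for c in node.children)
        assert child_sum <= res.counts[node.name]
        for c in node.children:
            check(c)

    check(tree)
    assert res.counts["CD45+ leukocytes"] == res.n_pregated


def test_gating_invariant_to_event_order(cutoffs, pbmc_lineages):
    cfg = sim.profile_config("pbmc_default", 3000, seed=14, bead_fraction=0.0,
                             dead_fraction=0.0, doublet_rate=0.0)
    m, _ = sim.simulate_sample(cfg)
    t = gate.arcsinh_transform(m)
    tree = gate.build_gating_tree(pbmc_lineages)
    res = gate.apply_gating(t, tree, cutoffs)
    rng = np.random.default_rng(0)
    perm = rng.permutation(t.n_events)
    res2 = gate.apply_gating(
        cm.EventMatrix(t.values[perm], t.channel_meta.copy(),
                       np.arange(t.n_events, dtype=float), t.scale),
        tree, cutoffs)
    back = np.empty_like(res.assignments)
    back[perm] = res2.assignments
    assert np.array_equal(back, res.assignments)


def test_empty_tree_assigns_everything_to_root(cutoffs, pbmc_transformed):
    t, _ = pbmc_transformed
    root = gate.GateNode("CD45+ leukocytes", None, [])
    res = gate.apply_gating(t, root, cutoffs)
    assert res.assigned_to_leaf_fraction == 1.0  # root is the only leaf
    assert set(res.assignments) == {"CD45+ leukocytes"}


def test_overlapping_siblings_warn(cutoffs, pbmc_transformed):
    t, _ = pbmc_transformed
    root = gate.GateNode("CD45+ leukocytes", None, [])
    root.children = [gate.GateNode("all1", root.name, [("CD45", "pos")]),
                     gate.GateNode("all2", root.name, [("CD3", "pos"),
                                                       ("CD45", "pos")])]
    with pytest.warns(UserWarning, match="overlapping sibling"):
        gate.apply_gating(t, root, cutoffs)


def test_frequency_table_roundtrip(cutoffs, pbmc_lineages, pbmc_transformed):
    t, _ = pbmc_transformed
    keep, _ = gate.pregate(t, cutoffs)
    tree = gate.build_gating_tree(pbmc_lineages)
    res = gate.apply_gating(t, tree, cutoffs, mask=keep, sample_id="S1")
    tab = gate.frequency_table([res])
    assert list(tab.counts.index) == ["S1"]
    for name in tab.counts.columns:
        assert tab.frequencies.loc["S1", name] == pytest.approx(
            res.frequency(name))
    assert tab.frequencies.sum(axis=1).iloc[0] <= 1.0 + 1e-12
    with pytest.raises(ValueError, match="duplicate"):
        gate.frequency_table([res, res])
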