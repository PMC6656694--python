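import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy
from sklearn.metrics import matthews_corrcoef
from statsmodels.stats.multitest import multipletests

import cytomon as cm
from cytomon import gate, simulate as sim, stats
from cytomon.errors import ConfigurationError
from cytomon.stats import CohortTable
from conftest import make_matrix


# ---------------------------------------------------------------- coverage

def test_coverage_counts_and_fraction(cutoffs, panel):
    # one event with exactly 4 positive antigens, one with none
    antigens = panel.antigens
    row_pos = [3.0 if a in ("CD45", "CD3", "CD4", "CD27") else 0.1
               for a in antigens]
    row_neg = [0.1] * len(antigens)
    m = make_matrix(np.array([row_pos, row_neg]), names=antigens,
                    scale="arcsinh")
    rep = stats.antigen_coverage(m, cutoffs, k=4)
    assert list(rep.counts) == [4, 0]
    assert rep.fraction_ge_k == 0.5


def test_coverage_all_cutoffs_at_infinity(panel):
    big = gate.CutoffTable({a: gate.Cutoff(1e9) for a in panel.antigens})
    m = make_matrix(np.random.default_rng(0).uniform(0, 5, (100, 33)),
                    names=panel.antigens, scale="arcsinh")
    rep = stats.antigen_coverage(m, big)
    assert rep.counts.max() == 0 and rep.fraction_ge_k == 0.0


def test_coverage_missing_cutoff_named(panel):
    partial = gate.CutoffTable({"CD45": gate.Cutoff(1.5)})
    m = make_matrix(np.zeros((10, 33)), names=panel.antigens, scale="arcsinh")
    with pytest.raises(ConfigurationError, match="CD235ab|CD61|CD3"):
        stats.antigen_coverage(m, partial)


def test_coverage_invariant_under_channel_permutation(cutoffs, panel):
    rng = np.random.default_rng(4)
    vals = rng.uniform(0, 4, (500, 33))
    m = make_matrix(vals, names=panel.antigens, scale="arcsinh")
    perm = rng.permutation(33)
    mp = make_matrix(vals[:, perm], names=[panel.antigens[i] for i in perm],
                     scale="arcsinh")
    a = stats.antigen_coverage(m, cutoffs)
    b = stats.antigen_coverage(mp, cutoffs)
    assert np.array_equal(a.counts, b.counts)


# ------------------------------------------------------------- regression

def test_regression_identity_line():
    f = np.array([0.01, 0.05, 0.2, 0.5])
    r, slope, intercept, p = stats.replicate_regression(f, f)
    assert (r, slope, intercept) == pytest.approx((1.0, 1.0, 0.0))
    r2, slope2, _, _ = stats.replicate_regression(f, 2 * f)
    assert (r2, slope2) == pytest.approx((1.0, 2.0))


def test_regression_rejects_degenerate_input():
    with pytest.raises(ValueError, match="zero variance"):
        stats.replicate_regression([0.1, 0.1, 0.1], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError):
        stats.replicate_regression([0.1, 0.2], [0.1, 0.2])


# ------------------------------------------------------ sample clustering

def test_duplicated_samples_merge_at_height_zero():
    f = pd.DataFrame([[0.1, 0.9], [0.1, 0.9], [0.8, 0.2]])
    z, _ = stats.cluster_sample_profiles(f)
    assert z[0, 2] == 0.0
    assert frozenset((0, 1)) in stats.sibling_leaf_pairs(z, 3)
    # the distant sample joins last
    assert z[-1, 2] == z[:, 2].max()


def test_nan_frequencies_rejected():
    f = pd.DataFrame([[0.1, np.nan], [0.2, 0.3]])
    with pytest.raises(ValueError, match="NaN"):
        stats.cluster_sample_profiles(f)


def test_replicate_pairs_cluster_as_siblings(cutoffs, pbmc_lineages):
    """5 donors x 2 technical replicates: >=4/5 pairs are sibling leaves."""
    tree = gate.build_gating_tree(pbmc_lineages)
    rows, donors = [], []
    for d in range(5):
        cfg = sim.profile_config("pbmc_default", 8000, seed=300 + d,
                                 frequency_noise=0.3)
        for m, gt in sim.simulate_replicate_pair(cfg, 0.05):
            t = gate.arcsinh_transform(m)
            keep, _ = gate.pregate(t, cutoffs)
            res = gate.apply_gating(t, tree, cutoffs, mask=keep)
            rows.append([res.frequency(l) for l in res.leaf_names])
            donors.append(d)
    z, _ = stats.cluster_sample_profiles(pd.DataFrame(rows))
    sib = stats.sibling_leaf_pairs(z, 10)
    hits = sum(frozenset((2 * d, 2 * d + 1)) in sib for d in range(5))
    assert hits >= 4


# ---------------------------------------------------------- bootstrap SEM

def test_bootstrap_sem_constant_vector_is_zero():
    med, sem = stats.bootstrap_sem_median(np.full(50, 3.3), seed=0)
    assert med == 3.3
    assert sem == pytest.approx(0.0, abs=1e-12)


def test_bootstrap_sem_tracks_asymptotic_formulas():
    # uniform-like sample: SE(median) = 1/(2 f(m) sqrt(n)) with f = 1/(b-a)
    x = np.arange(1, 101, dtype=float)
    med, sem = stats.bootstrap_sem_median(x, n_boot=4000, seed=1)
    assert med == 50.5
    theory_unif = (x.max() - x.min()) / (2 * np.sqrt(x.size))
    assert abs(sem - theory_unif) / theory_unif < 0.15
    # normal sample: SE(median) = 1.2533 sigma / sqrt(n)
    g = np.random.default_rng(0).normal(0, 1, 1001)
    _, sem_g = stats.bootstrap_sem_median(g, n_boot=4000, seed=2)
    theory_norm = 1.2533 * g.std(ddof=1) / np.sqrt(g.size)
    assert abs(sem_g - theory_norm) / theory_norm < 0.15


def test_bootstrap_sem_monte_carlo_stability():
    x = np.random.default_rng(2).normal(0, 1, 200)
    _, s1 = stats.bootstrap_sem_median(x, n_boot=1000, seed=10)
    _, s2 = stats.bootstrap_sem_median(x, n_boot=1000, seed=11)
    assert abs(s1 - s2) / s1 < 0.10


def test_bootstrap_sem_input_validation():
    with pytest.raises(ValueError):
        stats.bootstrap_sem_median([1.0])
    with pytest.raises(ValueError):
        stats.bootstrap_sem_median([1.0, 2.0], n_boot=1)


# ---------------------------------------------------------------- agreement

def test_agreement_perfect_labels():
    lab = np.array(["A", "B", "A", "C"] * 10)
    rep = stats.agreement(lab, lab)
    assert (rep.per_population["mcc"] == 1.0).all()
    assert rep.macro["f1"] == 1.0


def test_agreement_worked_confusion_example():
    # TP=90, FN=10, FP=5, TN=895
    a = np.array(["P"] * 100 + ["N"] * 900)
    b = np.array(["P"] * 90 + ["N"] * 10 + ["P"] * 5 + ["N"] * 895)
    rep = stats.agreement(a, b, populations=["P"])
    expected = (90 * 895 - 5 * 10) / np.sqrt(95 * 100 * 900 * 905)
    assert rep.per_population.loc["P", "mcc"] == pytest.approx(expected,
                                                               abs=1e-12)
    assert expected == pytest.approx(0.91514, abs=5e-5)


def test_agreement_symmetric_in_mcc():
    rng = np.random.default_rng(0)
    a = rng.choice(["A", "B", "C"], 500)
    b = rng.choice(["A", "B", "C"], 500)
    ab = stats.agreement(a, b).per_population["mcc"]
    ba = stats.agreement(b, a).per_population["mcc"]
    assert np.allclose(ab, ba)


def test_agreement_random_labels_near_zero():
    rng = np.random.default_rng(1)
    a = rng.choice(["A", "B"], 20000)
    b = rng.choice(["A", "B"], 20000)
    rep = stats.agreement(a, b)
    assert np.all(np.abs(rep.per_population["mcc"]) < 0.05)


def test_mcc_brute_force_oracle_all_small_tables():
    """Enumerate all 2x2 confusion tables with total <= 20 and compare the
    closed form against sklearn on reconstructed label vectors."""
    for tp in range(0, 21):
        for fp in range(0, 21 - tp):
            for fn in range(0, 21 - tp - fp):
                for tn in range(0, 21 - tp - fp - fn):
                    if tp + fp + fn + tn == 0:
                        continue
                    y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
                    y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
                    ours = stats.mcc_from_counts(tp, fp, fn, tn)
                    theirs = matthews_corrcoef(y_true, y_pred)
                    assert ours == pytest.approx(theirs, abs=1e-12), \
                        (tp, fp, fn, tn)


def test_agreement_length_mismatch():
    with pytest.raises(ValueError):
        stats.agreement(["A"], ["A", "B"])


# ------------------------------------------------------------------ BH FDR

def _bh_bruteforce(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_pos, i in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        out[i] = min(1.0, min(candidates))
    return out


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=20))
def test_bh_fdr_matches_bruteforce_and_statsmodels(pvals):
    ours = stats.bh_fdr(pvals)
    brute = _bh_bruteforce(pvals)
    assert np.allclose(ours, brute, atol=1e-12)
    sm_adj = multipletests(pvals, method="fdr_bh")[1]
    assert np.allclose(ours, sm_adj, atol=1e-12)
    assert np.all(ours >= np.asarray(pvals) - 1e-15)  # FDR >= p


# ---------------------------------------------------- differential abundance

def _null_cohort(seed, n_pops=12, n_samples=28, n_events=20000, sd=0.3):
    rng = np.random.default_rng(seed)
    base = np.full(n_pops, 1.0 / n_pops)
    rows = []
    for _ in range(n_samples):
        logit = np.log(base) - np.log1p(-base)
        p = 1 / (1 + np.exp(-(logit + rng.normal(0, sd, n_pops))))
        rows.append(rng.multinomial(n_events, p / p.sum()))
    counts = pd.DataFrame(
        rows, columns=[f"P{i}" for i in range(n_pops)],
        index=pd.Index([f"S{i}" for i in range(n_samples)], name="sample_id"))
    meta = pd.DataFrame({"group": ["A"] * 6 + ["B"] * (n_samples - 6)},
                        index=counts.index)
    return CohortTable(counts, counts.sum(axis=1), meta)


def test_da_identical_groups_is_null():
    ct = _null_cohort(0)
    sym = CohortTable(pd.concat([ct.counts.iloc[:6]] * 2).set_axis(
        [f"S{i}" for i in range(12)]),
        pd.concat([ct.totals.iloc[:6]] * 2).set_axis(
            [f"S{i}" for i in range(12)]),
        pd.DataFrame({"group": ["A"] * 6 + ["B"] * 6},
                     index=[f"S{i}" for i in range(12)]))
    da = stats.differential_abundance(sym)
    assert np.all(np.abs(da["log2fc"]) < 1e-6)
    assert np.all(da["fdr"] > 0.99)


def test_da_zero_count_group_flagged():
    ct = _null_cohort(1)
    counts = ct.counts.copy()
    counts.loc[ct.metadata["group"] == "A", "P0"] = 0
    da = stats.differential_abundance(
        CohortTable(counts, ct.totals, ct.metadata))
    assert bool(da.loc["P0", "flagged"])
    assert da.loc["P0", "p"] == 1.0


def test_da_scale_invariance():
    """Doubling one sample's counts moves its offset, not the fold change."""
    ct = _null_cohort(2)
    da1 = stats.differential_abundance(ct)
    counts = ct.counts.copy()
    counts.iloc[0] = counts.iloc[0] * 2
    totals = counts.sum(axis=1)
    da2 = stats.differential_abundance(
        CohortTable(counts, totals, ct.metadata))
    assert np.allclose(da1["log2fc"], da2["log2fc"], atol=0.02)


def test_da_requires_two_groups():
    ct = _null_cohort(3)
    meta = ct.metadata.copy()
    meta["group"] = "A"
    with pytest.raises(ConfigurationError):
        stats.differential_abundance(CohortTable(ct.counts, ct.totals, meta))


def test_da_type_one_error_calibration():
    """1,000-rep null: per-population rejection at alpha=0.05 stays within
    [0.03, 0.07] for an exchangeable cohort."""
    rej = []
    for rep in range(1000):
        da = stats.differential_abundance(_null_cohort(rep))
        rej.append((da["p"] < 0.05).to_numpy())
    rates = np.array(rej).mean(axis=0)
    assert rates.mean() == pytest.approx(0.05, abs=0.02)
    assert np.all(rates >= 0.03) and np.all(rates <= 0.07), rates


def test_da_detects_bundled_group_effects():
    ct = sim.simulate_cohort_counts("bmt", 28, seed=9, n_events=40000)
    da = stats.differential_abundance(ct, ref_group="non-GvHD")
    assert da.loc["CD27- B cells", "fdr"] < 0.05
    assert da.loc["CD27- B cells", "log2fc"] < -1  # reduced in GvHD
    assert da.loc["Naive CD4 T cells", "fdr"] < 0.05
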