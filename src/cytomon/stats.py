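"""Coverage QC, reproducibility metrics, label agreement and differential
abundance.

Differential abundance follows the count-based strategy used for cluster
frequencies in cytometry: per population, a negative-binomial GLM of counts
with a log(sample total) offset and a group indicator, a method-of-moments
dispersion shrunk toward the cohort median, a Wald test on the group
coefficient (t reference with n-2 degrees of freedom, a small-sample
calibration verified by simulation), and Benjamini-Hochberg FDR across
populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.cluster import hierarchy

from .errors import ConfigurationError
from .io_fcs import EventMatrix


@dataclass
class CohortTable:
    """Per-sample per-population counts with group metadata."""

    counts: pd.DataFrame          # samples x populations
    totals: pd.Series             # per-sample pre-gated event count
    metadata: pd.DataFrame | None = None

    @property
    def frequencies(self) -> pd.DataFrame:
        return self.counts.div(self.totals, axis=0)

    def groups(self, column: str = "group") -> pd.Series:
        if self.metadata is None or column not in self.metadata.columns:
            raise ConfigurationError(f"no '{column}' column in cohort metadata")
        return self.metadata[column]


# ---------------------------------------------------------------------------
# panel coverage

@dataclass
class CoverageReport:
    counts: np.ndarray            # per-event number of positive antigens
    median_count: float
    fraction_ge_k: float
    k: int
    by_lineage: pd.DataFrame | None = None


def antigen_coverage(matrix: EventMatrix, cutoffs, k: int = 4,
                     labels: np.ndarray | None = None) -> CoverageReport:
    """Number of antigens per cell above their positivity cutoff.

    The statistic is invariant under channel permutation; it counts antibody
    channels only.
    """
    if matrix.scale not in ("arcsinh", "arcsinh_p995"):
        from .errors import ScaleError
        raise ScaleError("antigen_coverage requires transformed data")
    idx = matrix.indices_by_role("antibody")
    antigens = list(matrix.channel_meta["antigen"].iloc[idx])
    for a in antigens:
        if a not in cutoffs:
            raise ConfigurationError(f"missing cutoff for antigen '{a}'")
    thresh = np.array([cutoffs.primary(a) for a in antigens])
    counts = (matrix.values[:, idx] >= thresh).sum(axis=1)
    frac = float((counts >= k).mean()) if counts.size else 0.0
    by_lineage = None
    if labels is not None:
        df = pd.DataFrame({"lineage": labels, "count": counts})
        by_lineage = df.groupby("lineage")["count"].agg(
            median="median", fraction_ge_k=lambda c: float((c >= k).mean()))
    return CoverageReport(counts, float(np.median(counts)) if counts.size else 0.0,
                          frac, k, by_lineage)


# ---------------------------------------------------------------------------
# reproducibility

def replicate_regression(freq_a, freq_b):
    """OLS of replicate-B frequencies on replicate-A frequencies pooled over
    populations (and donors); returns (pearson r, slope, intercept, p)."""
    a = np.asarray(freq_a, dtype=float)
    b = np.asarray(freq_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need matched frequency vectors of length >= 3")
    if np.ptp(a) == 0:
        raise ValueError("zero variance in reference frequencies")
    res = sps.linregress(a, b)
    return float(res.rvalue), float(res.slope), float(res.intercept), \
        float(res.pvalue)


def cluster_sample_profiles(freq_matrix: pd.DataFrame, linkage: str = "complete",
                            metric: str = "euclidean"):
    """Agglomerative dendrogram over sample frequency profiles.

    Returns the scipy linkage matrix and the leaf order.
    """
    x = np.asarray(freq_matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.isnan(x).any():
        raise ValueError("NaN frequencies in profile matrix")
    z = hierarchy.linkage(x, method=linkage, metric=metric)
    order = hierarchy.leaves_list(z)
    return z, order


def sibling_leaf_pairs(z: np.ndarray, n_leaves: int) -> set[frozenset]:
    """Pairs of original samples merged directly at a leaf-leaf join."""
    out = set()
    for a, b, *_ in z:
        if a < n_leaves and b < n_leaves:
            out.add(frozenset((int(a), int(b))))
    return out


def bootstrap_sem_median(values, n_boot: int = 1000, seed: int = 0):
    """Median and its bootstrap standard error (resampling with replacement)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(x, size=(n_boot, x.size), replace=True), axis=1)
    return float(np.median(x)), float(meds.std(ddof=1))


# ---------------------------------------------------------------------------
# label agreement

def mcc_from_counts(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 by convention when any
    marginal factor is zero."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


@dataclass
class AgreementReport:
    per_population: pd.DataFrame
    macro: dict[str, float]


def agreement(labels_a, labels_b, populations: list[str] | None = None
              ) -> AgreementReport:
    """One-vs-rest precision/recall/F1/MCC per population between two
    labelings of the same events, with macro means."""
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if a.shape != b.shape:
        raise ValueError("labelings must have the same length")
    if populations is None:
        populations = sorted(set(a) | set(b))
    rows = []
    for pop in populations:
        pa, pb = a == pop, b == pop
        tp = int((pa & pb).sum())
        fp = int((~pa & pb).sum())
        fn = int((pa & ~pb).sum())
        tn = int((~pa & ~pb).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) \
            if precision + recall else 0.0
        rows.append({"population": pop, "TP": tp, "FP": fp, "FN": fn, "TN": tn,
                     "precision": precision, "recall": recall, "f1": f1,
                     "mcc": mcc_from_counts(tp, fp, fn, tn)})
    df = pd.DataFrame(rows).set_index("population")
    macro = {m: float(df[m].mean()) for m in ("precision", "recall", "f1", "mcc")}
    return AgreementReport(df, macro)


# ---------------------------------------------------------------------------
# multiple testing

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# differential abundance

def _mom_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int = 2) -> float:
    """Method-of-moments NB dispersion alpha in Var = mu + alpha mu^2.

    The residual sum is scaled by n/(n - n_params) to account for the
    degrees of freedom consumed by the fitted group means.
    """
    denom = float((mu ** 2).sum())
    if denom <= 0:
        return 0.0
    n = y.size
    correction = n / max(n - n_params, 1)
    return max(0.0, float(correction * (((y - mu) ** 2 - mu)).sum() / denom))


def differential_abundance(cohort: CohortTable, group_col: str = "group",
                           shrinkage: float = 0.5,
                           ref_group: str | None = None) -> pd.DataFrame:
    """Negative-binomial Wald test of per-population counts between two
    groups, with a log(total) offset and BH FDR across populations.

    The reported log2 fold change is for the non-reference group relative to
    ``ref_group`` (default: the lexicographically first group).
    """
    groups = cohort.groups(group_col)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ConfigurationError(
            f"differential abundance needs exactly 2 groups, got {levels}")
    if ref_group is None:
        ref_group = levels[0]
    alt_group = [g for g in levels if g != ref_group][0]
    for g in levels:
        if (groups == g).sum() < 2:
            raise ConfigurationError(f"group '{g}' has fewer than 2 samples")
    totals = cohort.totals.to_numpy(dtype=float)
    if np.any(totals <= 0):
        raise ConfigurationError("sample totals must be positive")
    ind = (groups == alt_group).to_numpy(dtype=float)
    X = sm.add_constant(ind)
    offset = np.log(totals)
    n_samples = len(groups)

    pops = list(cohort.counts.columns)
    ymat = cohort.counts.to_numpy(dtype=float)

    # dispersion: per-population method of moments around group means, then
    # shrunk toward the cohort median for stability at small n
    raw_alpha = np.zeros(len(pops))
    for j in range(len(pops)):
        y = ymat[:, j]
        mu = np.empty_like(y)
        for g in (0.0, 1.0):
            sel = ind == g
            rate = y[sel].sum() / totals[sel].sum()
            mu[sel] = rate * totals[sel]
        raw_alpha[j] = _mom_dispersion(y, np.maximum(mu, 1e-8))
    med_alpha = float(np.median(raw_alpha))
    alphas = shrinkage * med_alpha + (1 - shrinkage) * raw_alpha

    rows = []
    for j, pop in enumerate(pops):
        y = ymat[:, j]
        zero_a = y[ind == 0].sum() == 0
        zero_b = y[ind == 1].sum() == 0
        if zero_a or zero_b:
            rows.append({"population": pop, "log2fc": 0.0,
                         "dispersion": alphas[j], "stat": 0.0, "p": 1.0,
                         "flagged": True})
            continue
        family = sm.families.NegativeBinomial(alpha=max(alphas[j], 1e-8))
        fit = sm.GLM(y, X, family=family, offset=offset).fit()
        coef, se = fit.params[1], fit.bse[1]
        stat = coef / se if se > 0 else 0.0
        p = 2 * sps.t.sf(abs(stat), df=max(n_samples - 2, 1))
        rows.append({"population": pop, "log2fc": coef / np.log(2),
                     "dispersion": alphas[j], "stat": stat, "p": p,
                     "flagged": False})
    out = pd.DataFrame(rows).set_index("population")
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out
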