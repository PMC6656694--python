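"""Intensity transforms, cutoff estimation, pre-gating and sequential gating.

Mass-cytometry dual counts are arcsinh-transformed with a cofactor of 5 and,
for clustering, normalized to the 99.5th percentile of each channel.  Gating
evaluates conjunctions of marker-threshold clauses down a population tree:
``pos``/``neg`` compare against the primary cutoff of an antigen and
``high``/``low`` against its secondary cutoff.  An event descends from a node
only while exactly one child predicate holds; otherwise it stays assigned to
the node ("ungated at level").
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gaussian_kde

from . import normalize as _normalize
from .errors import ConfigurationError, ScaleError
from .io_fcs import EventMatrix
from .panel import LineageDefinition, PanelDefinition


@dataclass(frozen=True)
class TransformSpec:
    cofactor: float = 5.0
    percentile: float = 99.5

    def __post_init__(self):
        if self.cofactor <= 0:
            raise ConfigurationError("cofactor must be positive")
        if not (0 < self.percentile <= 100):
            raise ConfigurationError("percentile must be in (0, 100]")


@dataclass(frozen=True)
class Cutoff:
    primary: float
    secondary: float | None = None
    provenance: str = "manual"

    def __post_init__(self):
        if self.secondary is not None and not self.secondary > self.primary:
            raise ConfigurationError(
                f"secondary cutoff must exceed primary "
                f"({self.secondary} <= {self.primary})")


class CutoffTable:
    """Per-antigen primary (pos/neg) and secondary (low/high) cutoffs."""

    def __init__(self, cutoffs: dict[str, Cutoff]):
        self._c = dict(cutoffs)

    def __contains__(self, antigen: str) -> bool:
        return antigen in self._c

    def antigens(self) -> list[str]:
        return list(self._c)

    def primary(self, antigen: str) -> float:
        try:
            return self._c[antigen].primary
        except KeyError:
            raise ConfigurationError(f"no cutoff defined for antigen '{antigen}'")

    def secondary(self, antigen: str) -> float:
        c = self._c.get(antigen)
        if c is None or c.secondary is None:
            raise ConfigurationError(
                f"no secondary cutoff defined for antigen '{antigen}'")
        return c.secondary

    def rescale(self, divisors: dict[str, float]) -> "CutoffTable":
        """Divide cutoffs per antigen (e.g. by the channel's 99.5th pct)."""
        out = {}
        for a, c in self._c.items():
            d = float(divisors.get(a, 1.0))
            out[a] = Cutoff(c.primary / d,
                            None if c.secondary is None else c.secondary / d,
                            c.provenance)
        return CutoffTable(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"antigen": a, "primary": c.primary, "secondary": c.secondary,
              "provenance": c.provenance} for a, c in self._c.items()]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CutoffTable":
        return cls({
            r.antigen: Cutoff(float(r.primary),
                              None if pd.isna(r.secondary) else float(r.secondary),
                              getattr(r, "provenance", "manual"))
            for r in df.itertuples()
        })


def default_cutoffs(panel: PanelDefinition) -> CutoffTable:
    """Packaged cutoffs: one default pair for every antibody channel plus
    auxiliary-channel thresholds (DNA, viability, event length, beads)."""
    ref = importlib.resources.files("cytomon.data").joinpath("cutoffs_default.yaml")
    raw = yaml.safe_load(ref.read_text())
    prov = raw.get("provenance", "manual")
    spec = raw["antigens"]
    out: dict[str, Cutoff] = {}
    for antigen in panel.antigens:
        entry = spec.get(antigen, spec["default"])
        out[antigen] = Cutoff(entry["primary"], entry.get("secondary"), prov)
    for name, entry in raw.get("auxiliary", {}).items():
        out[name] = Cutoff(entry["primary"], entry.get("secondary"), prov)
    return CutoffTable(out)


# ---------------------------------------------------------------------------
# transforms

def arcsinh_transform(matrix: EventMatrix, cofactor: float = 5.0) -> EventMatrix:
    """x -> asinh(x / cofactor) on every channel; raw -> arcsinh."""
    if matrix.scale != "raw":
        raise ScaleError(f"arcsinh_transform requires raw data, got '{matrix.scale}'")
    if cofactor <= 0:
        raise ConfigurationError("cofactor must be positive")
    return matrix.with_values(np.arcsinh(matrix.values / cofactor), scale="arcsinh")


def channel_percentiles(matrix: EventMatrix, p: float = 99.5) -> np.ndarray:
    if not (0 < p <= 100):
        raise ConfigurationError("percentile must be in (0, 100]")
    if matrix.n_events == 0:
        return np.ones(matrix.n_channels)
    return np.percentile(matrix.values, p, axis=0)


def percentile_normalize(matrix: EventMatrix, p: float = 99.5) -> EventMatrix:
    """Divide each channel by its p-th percentile; arcsinh -> arcsinh_p995.

    Channels whose percentile is zero are left unscaled with a warning.
    """
    if matrix.scale != "arcsinh":
        raise ScaleError(
            f"percentile_normalize requires arcsinh data, got '{matrix.scale}'")
    div = channel_percentiles(matrix, p)
    zero = div <= 0
    if zero.any():
        names = matrix.channel_meta.loc[zero, "name"].tolist()
        warnings.warn(f"zero {p}th percentile; channels left unscaled: {names}")
        div = np.where(zero, 1.0, div)
    return matrix.with_values(matrix.values / div, scale="arcsinh_p995")


def percentile_divisors(matrix: EventMatrix, p: float = 99.5) -> dict[str, float]:
    """Antigen -> percentile divisor map (for rescaling a CutoffTable)."""
    div = channel_percentiles(matrix, p)
    return {a: (float(d) if d > 0 else 1.0)
            for a, d in zip(matrix.channel_meta["antigen"], div)}


# ---------------------------------------------------------------------------
# cutoff estimation

def _modes(density: np.ndarray) -> list[int]:
    idx = [i for i in range(len(density))
           if (i == 0 or density[i] > density[i - 1])
           and (i == len(density) - 1 or density[i] >= density[i + 1])]
    return sorted(idx, key=lambda i: -density[i])


def estimate_cutoffs(matrix: EventMatrix, antigens: list[str],
                     secondary: bool = False, grid_size: int = 512,
                     min_mode_ratio: float = 0.03) -> CutoffTable:
    """Density-based cutoffs: the deepest valley between the two largest
    modes of a kernel-density estimate; for unimodal channels, the 99th
    percentile of a half-Gaussian fitted to the noise mode."""
    if matrix.scale not in ("arcsinh", "arcsinh_p995"):
        raise ScaleError("estimate_cutoffs requires transformed data")
    if matrix.n_events < 100:
        raise ValueError("insufficient events for density estimation (<100)")
    out: dict[str, Cutoff] = {}
    for antigen in antigens:
        x = matrix.get(antigen)
        if x.size > 20000:  # deterministic thinning keeps KDE cheap
            x = x[:: x.size // 20000 + 1]
        lo, hi = float(x.min()), float(x.max())
        if hi - lo < 1e-9:
            out[antigen] = Cutoff(lo + 1e-6, None, "estimated")
            continue
        kde = gaussian_kde(x)
        grid = np.linspace(lo, hi, grid_size)
        dens = kde(grid)
        modes = _modes(dens)
        major = [m for m in modes if dens[m] >= min_mode_ratio * dens[modes[0]]]
        if len(major) >= 2:
            m1, m2 = sorted(major[:2])
            valley = m1 + int(np.argmin(dens[m1:m2 + 1]))
            primary = float(grid[valley])
            sec = float(0.5 * (grid[valley] + grid[max(m1, m2)])) if secondary else None
        else:
            mode = float(grid[modes[0]])
            below = x[x <= mode]
            sigma = float(np.sqrt(np.mean((below - mode) ** 2))) if below.size else \
                float(np.std(x))
            primary = mode + 2.326 * max(sigma, 1e-6)
            sec = None
        out[antigen] = Cutoff(primary, sec, "estimated")
    return CutoffTable(out)


# ---------------------------------------------------------------------------
# gating tree

_RELATIONS = ("pos", "neg", "high", "low")


@dataclass
class GateNode:
    name: str
    parent: str | None
    clauses: list[tuple[str, str]] = field(default_factory=list)
    children: list["GateNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


def build_gating_tree(lineages: list[LineageDefinition]) -> GateNode:
    """Turn lineage marker-sign definitions into a gating tree."""
    nodes = {ld.name: GateNode(ld.name, ld.parent, list(ld.clauses))
             for ld in lineages}
    root = None
    for ld in lineages:
        if ld.parent is None:
            root = nodes[ld.name]
        else:
            nodes[ld.parent].children.append(nodes[ld.name])
    if root is None:
        raise ConfigurationError("lineage table has no root population")
    return root


def _eval_clauses(matrix: EventMatrix, clauses: list[tuple[str, str]],
                  cutoffs: CutoffTable, idx: np.ndarray) -> np.ndarray:
    ok = np.ones(idx.size, dtype=bool)
    for antigen, rel in clauses:
        v = matrix.values[idx, matrix.column_index(antigen=antigen)]
        if rel == "pos":
            ok &= v >= cutoffs.primary(antigen)
        elif rel == "neg":
            ok &= v < cutoffs.primary(antigen)
        elif rel == "high":
            ok &= v >= cutoffs.secondary(antigen)
        elif rel == "low":
            ok &= v <= cutoffs.secondary(antigen)
        else:
            raise ConfigurationError(f"unknown relation '{rel}'")
    return ok


@dataclass
class GatingResult:
    """Per-event deepest node assignment and per-node counts/frequencies.

    Frequencies are fractions of pre-gated cells; the assigned-to-leaf
    fraction is the share of pre-gated cells that reached a leaf population.
    """

    assignments: np.ndarray  # per pre-gated event: name of deepest node
    counts: dict[str, int]   # events that reached each node (incl. deeper)
    n_pregated: int
    leaf_names: list[str]
    sample_id: str = ""

    def frequency(self, name: str) -> float:
        return self.counts.get(name, 0) / self.n_pregated if self.n_pregated else 0.0

    @property
    def frequencies(self) -> dict[str, float]:
        return {k: v / self.n_pregated for k, v in self.counts.items()} \
            if self.n_pregated else {k: 0.0 for k in self.counts}

    @property
    def assigned_to_leaf_fraction(self) -> float:
        if self.n_pregated == 0:
            return 0.0
        leaf = set(self.leaf_names)
        return float(np.isin(self.assignments, list(leaf)).mean())


def apply_gating(matrix: EventMatrix, tree: GateNode, cutoffs: CutoffTable,
                 mask: np.ndarray | None = None, sample_id: str = "",
                 overlap_warn: float = 0.01) -> GatingResult:
    """Depth-first gating of pre-gated events down the population tree."""
    if matrix.scale not in ("arcsinh", "arcsinh_p995"):
        raise ScaleError("apply_gating requires transformed data")
    idx0 = np.flatnonzero(mask) if mask is not None else np.arange(matrix.n_events)
    assignments = np.full(idx0.size, tree.name, dtype=object)
    counts: dict[str, int] = {}
    pos_of = {int(e): i for i, e in enumerate(idx0)}

    def descend(node: GateNode, idx: np.ndarray):
        counts[node.name] = counts.get(node.name, 0) + idx.size
        if not node.children or idx.size == 0:
            return
        match = np.zeros((idx.size, len(node.children)), dtype=bool)
        for j, child in enumerate(node.children):
            match[:, j] = _eval_clauses(matrix, child.clauses, cutoffs, idx)
        n_match = match.sum(axis=1)
        multi = n_match > 1
        if idx.size and multi.mean() > overlap_warn:
            both = np.flatnonzero(match[multi][0])[:2]
            warnings.warn(
                f"overlapping sibling gates under '{node.name}': "
                f"'{node.children[both[0]].name}' and "
                f"'{node.children[both[1]].name}' "
                f"({multi.mean():.1%} of events match both)")
        for j, child in enumerate(node.children):
            take = idx[match[:, j] & (n_match == 1)]
            if take.size:
                rows = np.fromiter((pos_of[int(e)] for e in take), dtype=int,
                                   count=take.size)
                assignments[rows] = child.name
            descend(child, take)

    # ensure zero counts for unreached nodes
    stack = [tree]
    while stack:
        n = stack.pop()
        counts.setdefault(n.name, 0)
        stack.extend(n.children)
    counts[tree.name] = 0
    descend(tree, idx0)

    leaf_names = []
    stack = [tree]
    while stack:
        n = stack.pop()
        if n.is_leaf():
            leaf_names.append(n.name)
        stack.extend(n.children)
    return GatingResult(assignments, counts, idx0.size, leaf_names, sample_id)


# ---------------------------------------------------------------------------
# pre-gating

def pregate(matrix: EventMatrix, cutoffs: CutoffTable,
            granulocyte_matrix: bool = False,
            bead_mask: np.ndarray | None = None
            ) -> tuple[np.ndarray, pd.DataFrame]:
    """Sequential pre-gating to non-bead, DNA+, single, live, CD45+,
    CD235ab/CD61- (and, for granulocyte-containing matrices, non-neutrophil)
    events.  Returns the boolean keep-mask and a per-stage attrition report.
    """
    if matrix.scale not in ("arcsinh", "arcsinh_p995"):
        raise ScaleError("pregate requires transformed data")
    v = matrix.values
    stages: list[tuple[str, np.ndarray]] = []

    def col(antigen: str, stage: str) -> np.ndarray:
        try:
            return v[:, matrix.column_index(antigen=antigen)]
        except KeyError as exc:
            raise ConfigurationError(
                f"pre-gating stage '{stage}' requires channel '{antigen}'"
            ) from exc

    if bead_mask is None:
        bead_mask = _normalize.identify_beads(matrix, cutoffs=cutoffs)
    stages.append(("non-beads", ~bead_mask))

    dna_ok = (col("DNA1", "DNA+") >= cutoffs.primary("DNA1")) & \
             (col("DNA2", "DNA+") >= cutoffs.primary("DNA2"))
    stages.append(("DNA+", dna_ok))

    singlet = (col("DNA1", "singlets") <= cutoffs.secondary("DNA1")) & \
              (col("DNA2", "singlets") <= cutoffs.secondary("DNA2")) & \
              (col("Event_length", "singlets") < cutoffs.primary("Event_length"))
    stages.append(("singlets", singlet))

    stages.append(("live", col("Cisplatin", "live") <= cutoffs.primary("Cisplatin")))
    stages.append(("CD45+", col("CD45", "CD45+") >= cutoffs.primary("CD45")))
    stages.append(("CD235ab/CD61-",
                   (col("CD235ab", "CD235ab/CD61-") < cutoffs.primary("CD235ab"))
                   & (col("CD61", "CD235ab/CD61-") < cutoffs.primary("CD61"))))
    if granulocyte_matrix:
        neut = ((col("CD16", "non-neutrophils") >= cutoffs.primary("CD16"))
                & (col("CD14", "non-neutrophils") < cutoffs.primary("CD14"))
                & (col("HLA-DR", "non-neutrophils") < cutoffs.primary("HLA-DR"))
                & (col("CD11b", "non-neutrophils") >= cutoffs.secondary("CD11b")))
        stages.append(("non-neutrophils", ~neut))

    keep = np.ones(matrix.n_events, dtype=bool)
    rows = []
    for name, ok in stages:
        n_in = int(keep.sum())
        keep &= ok
        n_out = int(keep.sum())
        rows.append({"stage": name, "events_in": n_in, "events_out": n_out,
                     "fraction_kept": n_out / n_in if n_in else 1.0})
    return keep, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frequency tables

def frequency_table(results: list[GatingResult], metadata: pd.DataFrame | None = None,
                    populations: list[str] | None = None):
    """Samples x populations count/frequency table (leaf populations by
    default), joined with sample metadata when provided."""
    from .stats import CohortTable  # local import avoids a module cycle

    ids = [r.sample_id for r in results]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dup}")
    if populations is None:
        populations = results[0].leaf_names
    counts = pd.DataFrame(
        [[r.counts.get(p, 0) for p in populations] for r in results],
        index=pd.Index(ids, name="sample_id"), columns=populations)
    totals = pd.Series([r.n_pregated for r in results],
                       index=counts.index, name="n_pregated")
    if metadata is not None:
        metadata = metadata.set_index("sample_id").loc[counts.index] \
            if "sample_id" in metadata.columns else metadata.loc[counts.index]
    return CohortTable(counts=counts, totals=totals, metadata=metadata)


def rollup_frequencies(freqs: dict[str, float], lineages: list[LineageDefinition],
                       name: str) -> float:
    """Sum the frequencies of ``name`` and all of its descendants.

    Works on label->frequency maps where labels may sit at any tree depth
    (as produced by cluster annotation)."""
    from .panel import subtree
    return float(sum(freqs.get(n, 0.0) for n in subtree(name, lineages)))
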