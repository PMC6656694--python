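"""Self-organizing-map clustering, metaclustering and automatic annotation.

Events are quantized by a batch SOM (Euclidean distance on the selected
antigens), SOM nodes are agglomerated by average-linkage hierarchical
clustering of the codebook, and each metacluster is labeled by scoring its
median marker profile against the lineage marker-sign definitions: a clause
matches when the median lies on the required side of the antigen's cutoff,
the score is the matched fraction of clauses, and a metacluster receives the
deepest definition whose ancestors all score above the floor (default 0.9).

The codebook is seeded by greedy D^2-weighted sampling and refined with a
short-range shrinking neighborhood: the map is used as a quantizer (rare,
well-separated populations must keep dedicated nodes), not as a 2-D
visualization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import kmeans_plusplus

from .errors import ConfigurationError, ScaleError
from .io_fcs import EventMatrix
from .panel import (LineageDefinition, ROOT_POPULATION, ancestors,
                    children_map, depth, lineage_map, subtree)


@dataclass
class SOMModel:
    grid: tuple[int, int]
    codebook: np.ndarray            # nodes x channels
    channels: list[str]             # antigen names used for training
    seed: int
    epochs: int
    radius: tuple[float, float]

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]


def _grid_sqdist(grid: tuple[int, int]) -> np.ndarray:
    rows, cols = grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    diff = coords[:, None, :] - coords[None, :, :]
    return (diff ** 2).sum(-1)


def _bmu(x: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    d2 = (x ** 2).sum(1)[:, None] - 2 * x @ codebook.T + (codebook ** 2).sum(1)
    return np.argmin(d2, axis=1)


def train_som(matrix: EventMatrix, channels: list[str] | None = None,
              grid: tuple[int, int] = (10, 10), epochs: int = 10,
              seed: int = 0, radius: tuple[float, float] = (0.3, 0.05)
              ) -> SOMModel:
    """Batch SOM on the selected antigens; deterministic given the seed."""
    if matrix.scale == "raw":
        raise ScaleError("train_som requires transformed data")
    if channels is None:
        idx = matrix.indices_by_role("antibody")
        channels = list(matrix.channel_meta["antigen"].iloc[idx])
    cols = matrix.antigen_indices(channels)
    x = np.ascontiguousarray(matrix.values[:, cols])
    n_nodes = grid[0] * grid[1]
    if x.shape[0] < 10 * n_nodes:
        raise ValueError(
            f"too few events ({x.shape[0]}) for a {grid[0]}x{grid[1]} map "
            f"(needs >= {10 * n_nodes})")
    codebook, _ = kmeans_plusplus(x, n_clusters=n_nodes,
                                  random_state=int(seed) & 0x7FFFFFFF)
    codebook = codebook.astype(float)
    g2 = _grid_sqdist(grid)
    r0, r1 = radius
    for e in range(epochs):
        r = r0 + (r1 - r0) * (e / max(epochs - 1, 1))
        h = np.exp(-g2 / (2 * r * r))
        bmu = _bmu(x, codebook)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, x)
        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        numer = h @ sums
        denom = h @ counts
        ok = denom > 1e-12
        codebook[ok] = numer[ok] / denom[ok, None]
    return SOMModel(grid, codebook, list(channels), seed, epochs, radius)


def assign_events(model: SOMModel, matrix: EventMatrix,
                  idx: np.ndarray | None = None) -> np.ndarray:
    cols = matrix.antigen_indices(model.channels)
    x = matrix.values[:, cols] if idx is None else matrix.values[np.ix_(idx, cols)]
    return _bmu(x, model.codebook)


def metacluster(model: SOMModel, k: int) -> np.ndarray:
    """Average-linkage agglomeration of the codebook, cut at k metaclusters.

    Returns a zero-based node -> metacluster map; singletons are permitted.
    """
    if not (1 <= k <= model.n_nodes):
        raise ValueError(f"k must lie in [1, {model.n_nodes}], got {k}")
    if k == model.n_nodes:
        return np.arange(model.n_nodes)
    z = hierarchy.linkage(model.codebook, method="average", metric="euclidean")
    return hierarchy.fcluster(z, t=k, criterion="maxclust") - 1


def metacluster_profiles(matrix: EventMatrix, node_of_event: np.ndarray,
                         meta_of_node: np.ndarray,
                         idx: np.ndarray | None = None
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Median antibody-marker profile and size per metacluster."""
    ab = matrix.indices_by_role("antibody")
    antigens = list(matrix.channel_meta["antigen"].iloc[ab])
    values = matrix.values[:, ab] if idx is None else matrix.values[np.ix_(idx, ab)]
    mc = meta_of_node[node_of_event]
    profs, sizes = {}, {}
    for m in np.unique(mc):
        sel = mc == m
        profs[int(m)] = np.median(values[sel], axis=0)
        sizes[int(m)] = int(sel.sum())
    profiles = pd.DataFrame.from_dict(profs, orient="index", columns=antigens)
    return profiles, pd.Series(sizes, name="size")


# ---------------------------------------------------------------------------
# annotation

UNASSIGNED = "Unassigned"


def _clause_matches(median: pd.Series, antigen: str, rel: str, cutoffs) -> bool:
    v = median[antigen]
    if rel == "pos":
        return bool(v >= cutoffs.primary(antigen))
    if rel == "neg":
        return bool(v < cutoffs.primary(antigen))
    if rel == "high":
        return bool(v >= cutoffs.secondary(antigen))
    if rel == "low":
        return bool(v <= cutoffs.secondary(antigen))
    raise ConfigurationError(f"unknown relation '{rel}'")


def definition_score(median: pd.Series, definition: LineageDefinition,
                     cutoffs) -> float:
    clauses = definition.clauses
    if not clauses:
        return 1.0
    matched = sum(_clause_matches(median, a, rel, cutoffs) for a, rel in clauses)
    return matched / len(clauses)


@dataclass
class ClusterLabeling:
    node_to_meta: np.ndarray
    meta_label: dict[int, str]
    profiles: pd.DataFrame
    scores: dict[int, float]
    score_floor: float

    def label_events(self, node_of_event: np.ndarray) -> np.ndarray:
        mc = self.node_to_meta[node_of_event]
        return np.array([self.meta_label[int(m)] for m in mc], dtype=object)


def annotate_clusters(profiles: pd.DataFrame, lineages: list[LineageDefinition],
                      cutoffs, score_floor: float = 0.9,
                      root: str = ROOT_POPULATION,
                      node_to_meta: np.ndarray | None = None) -> ClusterLabeling:
    """Label each metacluster with the deepest lineage definition whose
    every ancestor (down to ``root``) scores at least ``score_floor``.

    Ties break toward the more specific (deeper) definition, then the larger
    score, then the lexicographically first name.  A metacluster failing the
    floor at the root is labeled Unassigned.
    """
    by_name = lineage_map(lineages)
    if root not in by_name:
        raise ConfigurationError(f"root population '{root}' not defined")
    candidates = [by_name[n] for n in subtree(root, lineages)]
    meta_label: dict[int, str] = {}
    scores: dict[int, float] = {}
    for m in profiles.index:
        med = profiles.loc[m]
        s = {d.name: definition_score(med, d, cutoffs) for d in candidates}
        valid = []
        for d in candidates:
            chain = [d.name] + [a for a in ancestors(d.name, lineages)
                                if a in s or a == root]
            chain = [c for c in chain if c in s]
            if all(s[c] >= score_floor for c in chain):
                valid.append(d)
        if not valid:
            meta_label[int(m)] = UNASSIGNED
            scores[int(m)] = s.get(root, 0.0)
            continue
        best = sorted(
            valid,
            key=lambda d: (-depth(d.name, lineages), -s[d.name], d.name))[0]
        meta_label[int(m)] = best.name
        scores[int(m)] = s[best.name]
    return ClusterLabeling(
        node_to_meta if node_to_meta is not None
        else np.arange(len(profiles)), meta_label, profiles, scores, score_floor)


# ---------------------------------------------------------------------------
# subclustering and the recursive annotation pipeline

def _auto_grid(n_events: int, n_defs: int) -> tuple[int, int]:
    n_nodes = min(max(16, 8 * n_defs), n_events // 10, 64)
    side = max(2, int(math.floor(math.sqrt(n_nodes))))
    return (side, side)


def subcluster(matrix: EventMatrix, labels: np.ndarray, lineage: str,
               lineages: list[LineageDefinition], cutoffs,
               grid: tuple[int, int] | None = None, k: int | None = None,
               seed: int = 0, min_events: int = 200,
               score_floor: float = 0.9) -> np.ndarray:
    """Re-cluster one lineage's events against its child definitions.

    Returns a refined copy of ``labels``; labels outside the lineage subtree
    are untouched.  With fewer than ``min_events`` events the call warns and
    returns the labels unchanged.
    """
    sub_names = subtree(lineage, lineages)
    if len(sub_names) < 2:
        return labels.copy()
    idx = np.flatnonzero(np.isin(labels, sub_names))
    if idx.size < min_events:
        warnings.warn(
            f"subclustering '{lineage}' skipped: {idx.size} events "
            f"(< {min_events})")
        return labels.copy()
    sub_defs = [d for d in lineages if d.name in sub_names]
    channels = sorted({a for d in sub_defs for a in d.antigens})
    if grid is None:
        grid = _auto_grid(idx.size, len(sub_defs) - 1)
    if k is None:
        k = min(grid[0] * grid[1], len(sub_defs) + 5)
    model = train_som(matrix.subset(idx), channels=channels, grid=grid,
                      seed=seed)
    node_of_event = assign_events(model, matrix, idx=idx)
    meta_of_node = metacluster(model, k)
    profiles, _ = metacluster_profiles(matrix, node_of_event, meta_of_node,
                                       idx=idx)
    labeling = annotate_clusters(profiles, lineages, cutoffs,
                                 score_floor=score_floor, root=lineage,
                                 node_to_meta=meta_of_node)
    out = labels.copy()
    out[idx] = labeling.label_events(node_of_event)
    return out


def cluster_and_annotate(matrix: EventMatrix, lineages: list[LineageDefinition],
                         cutoffs, mask: np.ndarray | None = None,
                         channels: list[str] | None = None,
                         grid: tuple[int, int] = (10, 10), k: int = 30,
                         seed: int = 0, min_events: int = 200,
                         score_floor: float = 0.9, recursive: bool = True
                         ) -> tuple[np.ndarray, list[dict]]:
    """Full annotation pass: top-level SOM + metaclustering + labeling, then
    recursive subclustering of every internal lineage with enough events.

    Returns a full-length per-event label array (the empty string outside
    ``mask``) and an audit trail of the clustering stages.
    """
    idx0 = np.flatnonzero(mask) if mask is not None else np.arange(matrix.n_events)
    labels_full = np.full(matrix.n_events, "", dtype=object)
    audit: list[dict] = []

    model = train_som(matrix.subset(idx0), channels=channels, grid=grid,
                      seed=seed)
    node_of_event = assign_events(model, matrix, idx=idx0)
    meta_of_node = metacluster(model, k)
    profiles, sizes = metacluster_profiles(matrix, node_of_event, meta_of_node,
                                           idx=idx0)
    labeling = annotate_clusters(profiles, lineages, cutoffs,
                                 score_floor=score_floor,
                                 node_to_meta=meta_of_node)
    labels = labeling.label_events(node_of_event)
    audit.append({"stage": ROOT_POPULATION, "n_events": int(idx0.size),
                  "grid": grid, "k": k,
                  "labels": sorted(set(labeling.meta_label.values()))})

    if recursive:
        kids = children_map(lineages)
        sub_seeds = [int(s.generate_state(1)[0] % 2**31)
                     for s in np.random.SeedSequence(seed).spawn(len(lineages))]
        counter = 0
        queue = [c.name for c in kids.get(ROOT_POPULATION, [])]
        while queue:
            name = queue.pop(0)
            if not kids.get(name):
                continue
            sub_seed = sub_seeds[counter]
            counter += 1
            n_before = int(np.isin(labels, subtree(name, lineages)).sum())
            labels = subcluster(
                _masked_view(matrix, idx0), labels, name, lineages, cutoffs,
                seed=sub_seed, min_events=min_events, score_floor=score_floor)
            audit.append({"stage": name, "n_events": n_before,
                          "grid": None, "k": None, "labels": None})
            queue.extend(c.name for c in kids.get(name, []))

    labels_full[idx0] = labels
    return labels_full, audit


def _masked_view(matrix: EventMatrix, idx: np.ndarray) -> EventMatrix:
    """View of the pre-gated events so that subcluster label indices align."""
    return matrix.subset(idx)


def label_frequencies(labels: np.ndarray, lineages: list[LineageDefinition] | None
                      = None) -> dict[str, float]:
    """Label -> frequency of annotated (non-empty) events."""
    lab = labels[labels != ""]
    n = lab.size
    if n == 0:
        return {}
    uniq, cnt = np.unique(lab.astype(str), return_counts=True)
    return {u: c / n for u, c in zip(uniq, cnt)}
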