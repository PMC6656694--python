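"""Synthetic mass-cytometry data with ground truth.

Every downstream stage of the pipeline is testable without external data:
this module draws single samples, paired technical replicates, barcoded
pools and transplant cohorts whose per-event population labels, QC flags
(bead/doublet/dead) and per-sample true frequency vectors are known.

Marker intensities are truncated Gaussians on the arcsinh (cofactor 5)
scale, placed per population by its marker-sign definition: negative markers
sit at a low baseline, positives above the primary cutoff, ``high`` levels
above the secondary cutoff and dim levels between the two.  Values are
inverse-transformed to raw dual counts, optionally scaled by an
acquisition-time drift, and assembled with calibration-bead events (high in
all EQ-bead channels, DNA-negative), cisplatin-high dead cells and doublets
(raw sums of two cell events, which doubles DNA and event length).

Per-sample frequency variation is logit-normal, which preserves the group
median and keeps frequencies in (0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import SimulationConfigError
from .gate import CutoffTable, default_cutoffs
from .io_fcs import EventMatrix, channel_meta_from_panel
from .panel import (LineageDefinition, ancestors, lineage_map,
                    load_lineage_table, load_reference_panel)

ARCSINH_COFACTOR = 5.0

#: arcsinh-scale aux-channel (location, spread) shared by all cell templates
AUX_CELL = {
    "DNA1": (5.0, 0.25), "DNA2": (5.0, 0.25), "Cisplatin": (0.8, 0.30),
    "Event_length": (2.31, 0.115),  # asinh(length/5); raw length ~ 25
    "Bead": (0.2, 0.15),
    "BC1": (0.2, 0.15), "BC2": (0.2, 0.15), "BC3": (0.2, 0.15),
    "BC4": (0.2, 0.15), "BC5": (0.2, 0.15), "BC6": (0.2, 0.15),
}
DEAD_CISPLATIN = (3.5, 0.4)
BARCODE_ON = (4.5, 0.30)
BEAD_LEVEL = (5.3, 0.20)
#: antigens sharing a metal with the EQ calibration beads
EQ_BEAD_ANTIGENS = ("CD123", "CD45RA", "CD127", "PD-1")

DEFAULT_SPREAD = 0.30
BASELINE = (0.2, 0.25)


@dataclass
class PopulationTemplate:
    """Per-population arcsinh-scale marker distribution and frequency."""

    name: str
    frequency: float
    location: dict[str, float]
    spread: dict[str, float] = field(default_factory=dict)


@dataclass
class SimConfig:
    n_events: int
    seed: int
    templates: list[PopulationTemplate]
    bead_fraction: float = 0.0
    doublet_rate: float = 0.0
    dead_fraction: float = 0.0
    drift: Callable[[np.ndarray], np.ndarray] | None = None
    barcode_code: tuple[str, ...] | None = None
    frequency_noise: float = 0.0  # logit-normal sd of per-sample perturbation
    filler: str | None = None     # population absorbing renormalization
    duration: float = 600.0
    sample_id: str = "S1"

    def validate(self) -> None:
        if self.n_events <= 0:
            raise SimulationConfigError("n_events must be positive")
        for nm in ("bead_fraction", "doublet_rate", "dead_fraction"):
            x = getattr(self, nm)
            if not (0 <= x <= 1):
                raise SimulationConfigError(f"{nm} must lie in [0, 1]")
        if self.frequency_noise < 0:
            raise SimulationConfigError("frequency_noise must be >= 0")
        if not self.templates:
            raise SimulationConfigError("at least one template required")
        total = sum(t.frequency for t in self.templates)
        if abs(total - 1.0) > 1e-9:
            raise SimulationConfigError(
                f"template frequencies must sum to 1 (got {total})")


@dataclass
class GroundTruth:
    labels: np.ndarray
    is_bead: np.ndarray
    is_doublet: np.ndarray
    is_dead: np.ndarray
    true_frequencies: dict[str, float]
    barcode_ids: np.ndarray | None = None
    sample_id: str = "S1"


# ---------------------------------------------------------------------------
# template construction from lineage definitions

def _constraint_intervals(leaf: str, lineages: list[LineageDefinition],
                          cutoffs: CutoffTable) -> dict[str, tuple[float, float]]:
    by_name = lineage_map(lineages)
    out: dict[str, tuple[float, float]] = {}
    for name in [leaf] + ancestors(leaf, lineages):
        for antigen, rel in by_name[name].clauses:
            lo, hi = out.get(antigen, (0.0, math.inf))
            if rel == "pos":
                lo = max(lo, cutoffs.primary(antigen))
            elif rel == "neg":
                hi = min(hi, cutoffs.primary(antigen))
            elif rel == "high":
                lo = max(lo, cutoffs.secondary(antigen))
            elif rel == "low":
                hi = min(hi, cutoffs.secondary(antigen))
            if lo > hi:
                raise SimulationConfigError(
                    f"contradictory constraints for {antigen} on path to {leaf}")
            out[antigen] = (lo, hi)
    return out


def _pick_location(lo: float, hi: float, primary: float, secondary: float) -> float:
    if lo <= 0:
        if math.isinf(hi) or hi <= primary:
            return BASELINE[0]
        return 1.0  # dim-low: below the secondary cutoff, e.g. CD127 on Tregs
    if math.isinf(hi):
        return lo + (1.4 if lo >= secondary else 2.0)
    return 0.5 * (lo + hi)  # dim-positive band between the two cutoffs


def templates_from_lineages(
    lineages: list[LineageDefinition],
    frequencies: dict[str, float],
    cutoffs: CutoffTable | None = None,
    extras: dict[str, dict[str, float]] | None = None,
    spread: float = DEFAULT_SPREAD,
    min_positive: int = 4,
) -> list[PopulationTemplate]:
    """Derive per-leaf marker locations from the lineage tree.

    Locations are consistent with the marker-sign clauses along each leaf's
    ancestor path by construction; ``extras`` add realism (and coverage)
    beyond the clauses, and must stay within the constraint band.  Every
    template must place at least ``min_positive`` antigens above their
    primary cutoff, mirroring the panel's coverage guarantee.
    """
    panel = load_reference_panel()
    if cutoffs is None:
        cutoffs = default_cutoffs(panel)
    extras = extras or {}
    out = []
    for leaf_name, freq in frequencies.items():
        iv = _constraint_intervals(leaf_name, lineages, cutoffs)
        loc = {a: BASELINE[0] for a in panel.antigens}
        spd = {a: BASELINE[1] for a in panel.antigens}
        for antigen, (lo, hi) in iv.items():
            loc[antigen] = _pick_location(lo, hi, cutoffs.primary(antigen),
                                          cutoffs.secondary(antigen)
                                          if _has_secondary(cutoffs, antigen)
                                          else cutoffs.primary(antigen) * 2)
            spd[antigen] = spread
        for antigen, value in extras.get(leaf_name, {}).items():
            lo, hi = iv.get(antigen, (0.0, math.inf))
            if not (lo <= value <= hi):
                raise SimulationConfigError(
                    f"extra location {antigen}={value} for '{leaf_name}' "
                    f"violates constraint band [{lo}, {hi}]")
            loc[antigen] = value
            spd[antigen] = spread
        for aux, (m, s) in AUX_CELL.items():
            loc[aux] = m
            spd[aux] = s
        n_pos = sum(1 for a in panel.antigens if loc[a] >= cutoffs.primary(a))
        if n_pos < min_positive:
            raise SimulationConfigError(
                f"template '{leaf_name}' has only {n_pos} positive antigens "
                f"(requires >= {min_positive})")
        out.append(PopulationTemplate(leaf_name, freq, loc, spd))
    return out


def _has_secondary(cutoffs: CutoffTable, antigen: str) -> bool:
    try:
        cutoffs.secondary(antigen)
        return True
    except Exception:
        return False


def _bead_template(panel) -> tuple[dict[str, float], dict[str, float]]:
    loc = {a: 0.15 for a in panel.antigens}
    spd = {a: 0.10 for a in panel.antigens}
    for a in EQ_BEAD_ANTIGENS:
        loc[a], spd[a] = BEAD_LEVEL
    for aux, (m, s) in AUX_CELL.items():
        loc[aux], spd[aux] = m, s
    loc["DNA1"], loc["DNA2"] = 0.1, 0.1
    spd["DNA1"] = spd["DNA2"] = 0.1
    loc["Cisplatin"], spd["Cisplatin"] = 0.1, 0.1
    loc["Event_length"], spd["Event_length"] = 1.7, 0.15
    loc["Bead"], spd["Bead"] = BEAD_LEVEL
    return loc, spd


# ---------------------------------------------------------------------------
# bundled profiles

PBMC_DEFAULT_FREQUENCIES: dict[str, float] = {
    "Naive CD4 T cells": 0.12, "Central memory CD4 T cells": 0.07,
    "Effector memory CD4 T cells": 0.06, "Effector CD4 T cells": 0.02,
    "Treg": 0.03,
    "Naive CD8 T cells": 0.06, "Central memory CD8 T cells": 0.03,
    "Effector memory CD8 T cells": 0.05, "Effector CD8 T cells": 0.04,
    "gd T cells": 0.02, "NKT cells": 0.01,
    "CD27- B cells": 0.08, "CD27+ B cells": 0.035, "Plasmablasts": 0.005,
    "CD56high CD16- NK cells": 0.02, "CD56low CD16+ NK cells": 0.10,
    "Classical monocytes": 0.17, "Intermediate monocytes": 0.02,
    "Non-classical monocytes": 0.03,
    "cDC": 0.015, "pDC": 0.01, "Basophils": 0.005,
}

#: BMT reconstitution profile: lineage medians T 29.0%, monocytes 27.0%,
#: NK 7.1%, B 2.5%; the HLA-DR-CD16+ filler absorbs the remainder and any
#: group-effect renormalization.
BMT_FREQUENCIES: dict[str, float] = {
    "Naive CD4 T cells": 0.0030, "Central memory CD4 T cells": 0.0450,
    "Effector memory CD4 T cells": 0.0420, "Effector CD4 T cells": 0.0200,
    "Naive Treg": 0.0050, "Memory Treg": 0.0150,
    "Naive CD8 T cells": 0.0050, "Central memory CD8 T cells": 0.0250,
    "Effector memory CD8 T cells": 0.0540, "Effector CD8 T cells": 0.0400,
    "Naive gd T cells": 0.0040, "Memory gd T cells": 0.0160,
    "NKT cells": 0.0050, "DN T cells": 0.0080, "DP T cells": 0.0030,
    "CD27- B cells": 0.0180, "CD27+ B cells": 0.0045,
    "Plasmablasts": 0.0010, "Transitional B cells": 0.0015,
    "CD56high CD16- NK cells": 0.0100, "CD56low CD16+ NK cells": 0.0560,
    "CD56high CD16+ NK cells": 0.0050,
    "Classical monocytes": 0.2000, "Intermediate monocytes": 0.0350,
    "Non-classical monocytes": 0.0350,
    "cDC": 0.0150, "pDC": 0.0080, "Basophils": 0.0040,
    "CD117+ progenitors": 0.0070,
    "HLA-DR-CD16+ cells": 0.3100,
}

FILLER_POPULATION = "HLA-DR-CD16+ cells"

#: Group-specific median frequencies (fractions of live leukocytes).
BMT_GVHD_EFFECTS: dict[str, dict[str, float]] = {
    "CD27- B cells": {"GvHD": 0.0044, "non-GvHD": 0.0333},
    "Naive CD4 T cells": {"GvHD": 0.0009, "non-GvHD": 0.0030},
}

EXTRA_LOCATIONS: dict[str, dict[str, float]] = {
    "Naive CD4 T cells": {"CD27": 3.5, "CD127": 3.5},
    "Central memory CD4 T cells": {"CD27": 3.5, "CD127": 3.5},
    "Effector memory CD4 T cells": {"CD127": 3.5},
    "Effector CD4 T cells": {"Tbet": 3.5, "CD127": 3.5},
    "Treg": {"CD45RO": 3.5},
    "Naive Treg": {"CCR7": 3.5},
    "Memory Treg": {},
    "Naive CD8 T cells": {"CD27": 3.5, "CD127": 3.5},
    "Central memory CD8 T cells": {"CD27": 3.5, "CD127": 3.5},
    "Effector memory CD8 T cells": {"CD127": 3.5},
    "Effector CD8 T cells": {"Tbet": 3.5},
    "gd T cells": {"CD27": 3.5},
    "Naive gd T cells": {"CD27": 3.5},
    "Memory gd T cells": {"CD27": 3.5},
    "NKT cells": {"CD56": 3.5},
    "DN T cells": {"CD27": 3.5, "CD127": 3.5},
    "DP T cells": {},
    "CD27- B cells": {"CD38": 2.25},
    "CD27+ B cells": {"HLA-DR": 3.5, "CD38": 2.25},
    "Plasmablasts": {"HLA-DR": 3.5},
    "Transitional B cells": {"HLA-DR": 3.5},
    "CD56high CD16- NK cells": {"CD38": 3.5, "Tbet": 3.5},
    "CD56low CD16+ NK cells": {"CD38": 3.5, "Tbet": 3.5},
    "CD56high CD16+ NK cells": {"CD38": 3.5, "Tbet": 3.5},
    "Classical monocytes": {"CD11b": 3.5, "CD11c": 3.5, "HLA-DR": 3.5},
    "Intermediate monocytes": {"CD11b": 3.5, "CD11c": 3.5, "HLA-DR": 3.5},
    "Non-classical monocytes": {"CD11b": 3.5, "CD11c": 3.5, "HLA-DR": 3.5},
    "cDC": {"CD33": 3.5, "CD11b": 3.5},
    "pDC": {"CD38": 3.5},
    "Basophils": {"CD38": 3.5},
    "HLA-DR-CD16+ cells": {"CD38": 3.5},
    "CD117+ progenitors": {"CD33": 3.5, "HLA-DR": 2.25},
}


def profile_config(profile: str, n_events: int, seed: int, **overrides) -> SimConfig:
    """Bundled single-sample profiles (``pbmc_default``)."""
    if profile != "pbmc_default":
        raise SimulationConfigError(
            f"unknown simulation profile '{profile}'; available: pbmc_default")
    lineages = load_lineage_table("pbmc_core")
    templates = templates_from_lineages(
        lineages, PBMC_DEFAULT_FREQUENCIES, extras=EXTRA_LOCATIONS)
    defaults = dict(bead_fraction=0.05, dead_fraction=0.03, doublet_rate=0.02)
    defaults.update(overrides)
    return SimConfig(n_events=n_events, seed=seed, templates=templates, **defaults)


# ---------------------------------------------------------------------------
# core generator

def _perturb_frequencies(freqs: np.ndarray, sd: float,
                         rng: np.random.Generator,
                         filler_idx: int | None = None) -> np.ndarray:
    """Logit-normal per-population perturbation (median-preserving).

    When a filler population is designated, it absorbs the renormalization so
    that every other population's median stays exactly at its parameter;
    otherwise the vector is rescaled to sum to one.
    """
    if sd <= 0:
        return freqs
    logit = np.log(freqs) - np.log1p(-freqs)
    p = 1.0 / (1.0 + np.exp(-(logit + rng.normal(0, sd, freqs.size))))
    if filler_idx is not None:
        rest = p.sum() - p[filler_idx]
        if rest < 1.0:
            p[filler_idx] = 1.0 - rest
            return p
    return p / p.sum()


def simulate_sample(config: SimConfig) -> tuple[EventMatrix, GroundTruth]:
    """Draw one sample; reproducible bit-for-bit given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = load_reference_panel()
    meta = channel_meta_from_panel(panel)
    channels = list(meta["antigen"])
    n_ch = len(channels)
    cis_col = channels.index("Cisplatin")

    names = [t.name for t in config.templates]
    base = np.array([t.frequency for t in config.templates])
    filler_idx = names.index(config.filler) if config.filler in names else None
    true_freq = _perturb_frequencies(base, config.frequency_noise, rng,
                                     filler_idx)

    loc_mat = np.array([[t.location.get(c, BASELINE[0]) for c in channels]
                        for t in config.templates])
    spd_mat = np.array([[t.spread.get(c, BASELINE[1]) for c in channels]
                        for t in config.templates])

    n = config.n_events
    n_beads = rng.binomial(n, config.bead_fraction)
    n_rest = n - n_beads
    n_doublets = rng.binomial(n_rest, config.doublet_rate)
    n_singlets = n_rest - n_doublets
    n_dead = rng.binomial(n_singlets, config.dead_fraction)

    n_cells = n_singlets + 2 * n_doublets
    cell_tpl = rng.choice(len(names), size=n_cells, p=true_freq) if n_cells else \
        np.empty(0, dtype=int)
    vals = rng.normal(loc_mat[cell_tpl], spd_mat[cell_tpl]) if n_cells else \
        np.empty((0, n_ch))
    if n_dead:
        vals[:n_dead, cis_col] = rng.normal(*DEAD_CISPLATIN, n_dead)
    if config.barcode_code:
        for ch in config.barcode_code:
            vals[:, channels.index(ch)] = rng.normal(*BARCODE_ON, n_cells)
    np.clip(vals, 0.0, None, out=vals)
    raw_cells = ARCSINH_COFACTOR * np.sinh(vals)

    raw_singlets = raw_cells[:n_singlets]
    raw_doublets = (raw_cells[n_singlets:n_singlets + n_doublets]
                    + raw_cells[n_singlets + n_doublets:])

    bead_loc, bead_spd = _bead_template(panel)
    bl = np.array([bead_loc.get(c, 0.15) for c in channels])
    bs = np.array([bead_spd.get(c, 0.10) for c in channels])
    bead_vals = np.clip(rng.normal(bl, bs, (n_beads, n_ch)), 0.0, None)
    raw_beads = ARCSINH_COFACTOR * np.sinh(bead_vals)

    raw = np.vstack([raw_singlets, raw_doublets, raw_beads])
    labels = np.concatenate([
        np.array(names, dtype=object)[cell_tpl[:n_singlets]],
        np.array(names, dtype=object)[cell_tpl[n_singlets:n_singlets + n_doublets]],
        np.full(n_beads, "bead", dtype=object)])
    is_bead = np.zeros(n, dtype=bool); is_bead[n_singlets + n_doublets:] = True
    is_doublet = np.zeros(n, dtype=bool)
    is_doublet[n_singlets:n_singlets + n_doublets] = True
    is_dead = np.zeros(n, dtype=bool); is_dead[:n_dead] = True

    order = rng.permutation(n)
    raw, labels = raw[order], labels[order]
    is_bead, is_doublet, is_dead = is_bead[order], is_doublet[order], is_dead[order]
    time = np.sort(rng.uniform(0, config.duration, n))

    if config.drift is not None:
        factors = np.asarray(config.drift(time / config.duration), dtype=float)
        if np.any(factors <= 0):
            raise SimulationConfigError("drift factors must be positive")
        mass = meta["role"].isin(
            ["antibody", "dna", "viability", "bead", "barcode"]).to_numpy()
        if factors.ndim == 1:
            raw[:, mass] *= factors[:, None]
        else:
            raw[:, mass] *= factors[:, mass]

    matrix = EventMatrix(raw, meta, time, scale="raw")
    gt = GroundTruth(labels, is_bead, is_doublet, is_dead,
                     dict(zip(names, true_freq.tolist())),
                     sample_id=config.sample_id)
    return matrix, gt


def simulate_replicate_pair(config: SimConfig, technical_noise_sd: float
                            ) -> list[tuple[EventMatrix, GroundTruth]]:
    """Two aliquots of the same donor acquired under inter-site variation.

    Both replicates share the donor's true frequency vector; each replicate
    applies an independent per-channel location shift with the given sd,
    modeling site-specific staining intensity differences.
    """
    if technical_noise_sd < 0:
        raise SimulationConfigError("technical_noise_sd must be >= 0")
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    donor_seed, *rep_seeds = [int(s.generate_state(1)[0] % 2**31)
                              for s in ss.spawn(3)]
    rng = np.random.default_rng(donor_seed)
    base = np.array([t.frequency for t in config.templates])
    true_freq = _perturb_frequencies(base, config.frequency_noise, rng)
    antigens = load_reference_panel().antigens

    out = []
    for r, seed in enumerate(rep_seeds):
        srng = np.random.default_rng(seed + 1_000_003)
        shift = {a: srng.normal(0, technical_noise_sd) for a in antigens} \
            if technical_noise_sd > 0 else {}
        templates = [
            PopulationTemplate(
                t.name, float(f),
                {c: max(v + shift.get(c, 0.0), 0.0) for c, v in t.location.items()},
                dict(t.spread))
            for t, f in zip(config.templates, true_freq)]
        rep = replace(config, seed=seed, templates=templates,
                      frequency_noise=0.0, sample_id=f"{config.sample_id}_r{r+1}")
        out.append(simulate_sample(rep))
    return out


# ---------------------------------------------------------------------------
# cohorts

def _apply_effects(base: dict[str, float], effect_table: dict[str, dict[str, float]],
                   group: str) -> dict[str, float]:
    freqs = dict(base)
    for pop, by_group in (effect_table or {}).items():
        if pop not in freqs:
            raise SimulationConfigError(
                f"effect table references unknown population '{pop}'")
        if group in by_group:
            freqs[pop] = by_group[group]
    delta = 1.0 - sum(freqs.values())
    freqs[FILLER_POPULATION] = freqs.get(FILLER_POPULATION, 0.0) + delta
    if freqs.get(FILLER_POPULATION, 0.0) <= 0:
        raise SimulationConfigError("group effects exceed the filler population")
    return freqs


def bmt_cohort_metadata(n_samples: int = 28) -> pd.DataFrame:
    """Sample sheet shaped like a transplant cohort: 15 donors sampled at
    days 30/90 for 28 samples total, 3 donors with GvHD (6 samples)."""
    rows = []
    for d in range(1, 4):
        for tp in ("d30", "d90"):
            rows.append((f"G{d:02d}_{tp}", f"G{d:02d}", tp, "GvHD"))
    for d in range(1, 11):
        for tp in ("d30", "d90"):
            rows.append((f"N{d:02d}_{tp}", f"N{d:02d}", tp, "non-GvHD"))
    rows.append(("N11_d30", "N11", "d30", "non-GvHD"))
    rows.append(("N12_d30", "N12", "d30", "non-GvHD"))
    df = pd.DataFrame(rows, columns=["sample_id", "donor", "time_point", "group"])
    return df.iloc[:n_samples].reset_index(drop=True)


def _cohort_configs(profile: str, n_samples: int,
                    group_assignment: list[str] | None,
                    effect_table: dict | None, seed: int, n_events: int,
                    frequency_noise: float
                    ) -> tuple[list[SimConfig], pd.DataFrame]:
    if profile != "bmt":
        raise SimulationConfigError(
            f"unknown cohort profile '{profile}'; available: bmt")
    metadata = bmt_cohort_metadata(n_samples)
    if group_assignment is not None:
        if len(group_assignment) != n_samples:
            raise SimulationConfigError("group_assignment must cover all samples")
        metadata = metadata.copy()
        metadata["group"] = list(group_assignment)
    if effect_table is None:
        effect_table = BMT_GVHD_EFFECTS
    lineages = load_lineage_table("bmt_subsets")
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(seed).spawn(n_samples)]
    configs = []
    for i, row in metadata.iterrows():
        freqs = _apply_effects(BMT_FREQUENCIES, effect_table, row["group"])
        templates = templates_from_lineages(lineages, freqs,
                                            extras=EXTRA_LOCATIONS)
        configs.append(SimConfig(
            n_events=n_events, seed=seeds[i], templates=templates,
            bead_fraction=0.03, dead_fraction=0.05, doublet_rate=0.02,
            frequency_noise=frequency_noise, filler=FILLER_POPULATION,
            sample_id=row["sample_id"]))
    return configs, metadata


def simulate_cohort(profile: str = "bmt", n_samples: int = 28,
                    group_assignment: list[str] | None = None,
                    effect_table: dict | None = None, seed: int = 0,
                    n_events: int = 40000, frequency_noise: float = 0.3,
                    lazy: bool = False):
    """Simulate a transplant cohort with group-specific population effects.

    Returns ``(samples, metadata)`` where samples is a list (or, with
    ``lazy=True``, an iterator) of ``(EventMatrix, GroundTruth)`` pairs.
    """
    configs, metadata = _cohort_configs(profile, n_samples, group_assignment,
                                        effect_table, seed, n_events,
                                        frequency_noise)
    gen = (simulate_sample(c) for c in configs)
    return (gen if lazy else list(gen)), metadata


def simulate_cohort_counts(profile: str = "bmt", n_samples: int = 28,
                           group_assignment: list[str] | None = None,
                           effect_table: dict | None = None, seed: int = 0,
                           n_events: int = 40000, frequency_noise: float = 0.3):
    """Cohort ground-truth count table (no per-event data): one multinomial
    draw per sample from its true frequency vector.  Used to study the
    differential-abundance stage in isolation."""
    from .stats import CohortTable
    if profile != "bmt":
        raise SimulationConfigError(
            f"unknown cohort profile '{profile}'; available: bmt")
    metadata = bmt_cohort_metadata(n_samples)
    if group_assignment is not None:
        if len(group_assignment) != n_samples:
            raise SimulationConfigError("group_assignment must cover all samples")
        metadata = metadata.copy()
        metadata["group"] = list(group_assignment)
    if effect_table is None:
        effect_table = BMT_GVHD_EFFECTS
    names = list(BMT_FREQUENCIES)
    filler_idx = names.index(FILLER_POPULATION)
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(seed).spawn(n_samples)]
    rows = []
    for i, row in metadata.iterrows():
        freqs = _apply_effects(BMT_FREQUENCIES, effect_table, row["group"])
        rng = np.random.default_rng(seeds[i])
        freq = _perturb_frequencies(np.array([freqs[n] for n in names]),
                                    frequency_noise, rng, filler_idx)
        rows.append(rng.multinomial(n_events, freq))
    counts = pd.DataFrame(rows, columns=names,
                          index=pd.Index(metadata["sample_id"], name="sample_id"))
    totals = counts.sum(axis=1).rename("n_pregated")
    return CohortTable(counts=counts, totals=totals,
                       metadata=metadata.set_index("sample_id"))


# ---------------------------------------------------------------------------
# barcoded pools

def simulate_barcoded_pool(configs: dict[str, SimConfig],
                           scheme: dict[str, tuple],
                           cross_doublet_fraction: float = 0.0,
                           seed: int = 0) -> tuple[EventMatrix, GroundTruth]:
    """Pool barcoded samples; a fraction of cross-sample doublets carries the
    union barcode pattern (sum of the two raw patterns)."""
    from .normalize import validate_scheme
    validate_scheme(scheme)
    missing = set(configs) - set(scheme)
    if missing:
        raise SimulationConfigError(f"samples without barcode codes: {missing}")
    if not (0 <= cross_doublet_fraction <= 1):
        raise SimulationConfigError("cross_doublet_fraction must lie in [0, 1]")

    parts, gts, ids = [], [], []
    for sample_id, cfg in configs.items():
        cfg = replace(cfg, barcode_code=tuple(scheme[sample_id]),
                      sample_id=sample_id)
        m, gt = simulate_sample(cfg)
        parts.append(m)
        gts.append(gt)
        ids.append(np.where(gt.is_bead, "unassigned", sample_id))
    meta = parts[0].channel_meta
    raw = np.vstack([m.values for m in parts])
    labels = np.concatenate([g.labels for g in gts])
    is_bead = np.concatenate([g.is_bead for g in gts])
    is_doublet = np.concatenate([g.is_doublet for g in gts])
    is_dead = np.concatenate([g.is_dead for g in gts])
    barcode_ids = np.concatenate(ids)

    rng = np.random.default_rng(seed)
    n_cross = rng.binomial(raw.shape[0], cross_doublet_fraction)
    if n_cross and len(parts) >= 2:
        sizes = np.array([m.n_events for m in parts])
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        pick_s = np.array([rng.choice(len(parts), 2, replace=False)
                           for _ in range(n_cross)])
        i1 = offsets[pick_s[:, 0]] + rng.integers(0, sizes[pick_s[:, 0]])
        i2 = offsets[pick_s[:, 1]] + rng.integers(0, sizes[pick_s[:, 1]])
        raw = np.vstack([raw, raw[i1] + raw[i2]])
        labels = np.concatenate([labels, labels[i1]])
        is_bead = np.concatenate([is_bead, np.zeros(n_cross, bool)])
        is_doublet = np.concatenate([is_doublet, np.ones(n_cross, bool)])
        is_dead = np.concatenate([is_dead, np.zeros(n_cross, bool)])
        barcode_ids = np.concatenate(
            [barcode_ids, np.full(n_cross, "unassigned", dtype=object)])

    n = raw.shape[0]
    order = rng.permutation(n)
    time = np.sort(rng.uniform(0, 600.0, n))
    matrix = EventMatrix(raw[order], meta.copy(), time, scale="raw")
    gt = GroundTruth(labels[order], is_bead[order], is_doublet[order],
                     is_dead[order],
                     {}, barcode_ids=barcode_ids[order], sample_id="pool")
    return matrix, gt
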