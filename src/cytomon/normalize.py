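"""Bead-based sensitivity-drift correction and barcode deconvolution.

Calibration beads (EQ four-element beads plus cerium-140) are spiked into
every acquisition.  Events positive in *all* bead channels and negative for
DNA are beads; their per-time-window median intensities yield a scalar
correction factor per window (median over bead channels of global/window
median), interpolated in time and multiplied into every mass channel.
Windows are defined in bead events (default 500), not seconds, so pauses in
acquisition do not distort the correction.

Debarcoding assigns pooled events back to samples by a k-of-n metal code:
barcode channels are rescaled to [0, 1] within each event, the top-k set is
matched against the scheme, and the separation between the k-th and
(k+1)-th intensity must clear a cutoff (default 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_fcs import EventMatrix

#: EQ four-element bead metals plus the cerium-140 bead channel.
BEAD_METALS = ("140Ce", "151Eu", "153Eu", "165Ho", "175Lu")


def _bead_columns(matrix: EventMatrix) -> list[int]:
    cols = []
    for metal in BEAD_METALS:
        try:
            cols.append(matrix.column_index(metal=metal))
        except KeyError:
            continue
    if not cols:
        raise ConfigurationError("no bead channels present in matrix")
    return cols


def _as_arcsinh(matrix: EventMatrix, cols: list[int]) -> np.ndarray:
    v = matrix.values[:, cols]
    return np.arcsinh(v / 5.0) if matrix.scale == "raw" else v


def identify_beads(matrix: EventMatrix, cutoffs=None,
                   bead_cutoff: float = 3.0, dna_cutoff: float = 2.5
                   ) -> np.ndarray:
    """Boolean bead mask: high in ALL bead channels and DNA-negative.

    Bead-cell doublets (bead-positive and DNA-positive) are excluded from
    both beads and cells downstream, because the bead mask complement still
    contains them only until the DNA/singlet stages remove them.
    """
    if cutoffs is not None:
        bead_cutoff = cutoffs.primary("Bead") if "Bead" in cutoffs else bead_cutoff
        dna_cutoff = cutoffs.primary("DNA1") if "DNA1" in cutoffs else dna_cutoff
    cols = _bead_columns(matrix)
    bead_sig = _as_arcsinh(matrix, cols)
    all_high = (bead_sig >= bead_cutoff).all(axis=1)
    dna_cols = [matrix.column_index(antigen=a) for a in ("DNA1", "DNA2")]
    dna = _as_arcsinh(matrix, dna_cols)
    return all_high & (dna < dna_cutoff).all(axis=1)


@dataclass
class BeadModel:
    bead_mask: np.ndarray
    window_times: np.ndarray          # median bead time per window
    window_medians: pd.DataFrame      # windows x bead channels (raw medians)
    reference: np.ndarray             # global raw median per bead channel
    factors: np.ndarray               # scalar correction per window
    bead_columns: list[int] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.factors)

    def factor_at(self, time: np.ndarray) -> np.ndarray:
        if self.n_windows == 0:
            return np.ones_like(time, dtype=float)
        return np.interp(time, self.window_times, self.factors)


def fit_bead_model(matrix: EventMatrix, bead_mask: np.ndarray | None = None,
                   window_beads: int = 500, cutoffs=None) -> BeadModel:
    """Estimate per-window correction factors from bead events (raw scale)."""
    if bead_mask is None:
        bead_mask = identify_beads(matrix, cutoffs=cutoffs)
    cols = _bead_columns(matrix)
    idx = np.flatnonzero(bead_mask)
    n_windows = idx.size // window_beads
    empty = BeadModel(bead_mask, np.empty(0), pd.DataFrame(), np.empty(0),
                      np.empty(0), cols)
    if idx.size == 0:
        warnings.warn("no bead events found; identity normalization applied")
        return empty
    if n_windows < 2 or idx.size // max(n_windows, 1) < 10:
        warnings.warn(
            f"insufficient beads for windowed normalization "
            f"({idx.size} beads, {n_windows} windows); identity applied")
        return empty
    bead_vals = matrix.values[idx][:, cols]
    bead_time = matrix.time[idx]
    reference = np.median(bead_vals, axis=0)
    bounds = np.linspace(0, idx.size, n_windows + 1).astype(int)
    times, medians, factors = [], [], []
    for w in range(n_windows):
        sl = slice(bounds[w], bounds[w + 1])
        med = np.median(bead_vals[sl], axis=0)
        if np.any(med <= 0):
            warnings.warn(f"zero bead median in window {w}; window dropped")
            continue
        times.append(np.median(bead_time[sl]))
        medians.append(med)
        factors.append(float(np.median(reference / med)))
    if len(factors) < 2:
        warnings.warn("fewer than 2 usable bead windows; identity applied")
        return empty
    return BeadModel(bead_mask, np.asarray(times),
                     pd.DataFrame(medians, columns=[str(c) for c in cols]),
                     reference, np.asarray(factors), cols)


def bead_normalize(matrix: EventMatrix, bead_model: BeadModel | None = None,
                   window_beads: int = 500, cutoffs=None
                   ) -> tuple[EventMatrix, BeadModel]:
    """Multiply every mass channel by the interpolated per-event factor.

    Event count, channel count and non-mass channels (event length) are
    preserved; bead channels are corrected too and retained for audit.
    """
    if matrix.scale != "raw":
        from .errors import ScaleError
        raise ScaleError("bead_normalize requires raw-scale data")
    if bead_model is None:
        bead_model = fit_bead_model(matrix, window_beads=window_beads,
                                    cutoffs=cutoffs)
    factors = bead_model.factor_at(matrix.time)
    mass = matrix.channel_meta["role"].isin(
        ["antibody", "dna", "viability", "bead", "barcode"]).to_numpy()
    values = matrix.values.copy()
    values[:, mass] *= factors[:, None]
    return matrix.with_values(values), bead_model


# ---------------------------------------------------------------------------
# debarcoding

@dataclass
class BarcodeAssignment:
    labels: np.ndarray        # per-event sample label or "unassigned"
    separation: np.ndarray    # k-th minus (k+1)-th rescaled intensity
    yields: dict[str, float]  # per-sample fraction of events


def validate_scheme(scheme: dict[str, tuple]) -> int:
    """Check codes are same-k and pairwise distinct; returns k."""
    codes = [frozenset(c) for c in scheme.values()]
    if len(set(codes)) != len(codes):
        raise ConfigurationError("duplicate barcode codes in scheme")
    ks = {len(c) for c in codes}
    if len(ks) != 1:
        raise ConfigurationError("all barcode codes must use the same k")
    return ks.pop()


def debarcode(matrix: EventMatrix, scheme: dict[str, tuple],
              separation_cutoff: float = 0.1) -> BarcodeAssignment:
    """Assign pooled events to samples by their top-k barcode channels."""
    if not (0 <= separation_cutoff <= 1):
        raise ConfigurationError("separation cutoff must lie in [0, 1]")
    k = validate_scheme(scheme)
    bc_idx = matrix.indices_by_role("barcode")
    if bc_idx.size == 0:
        raise ConfigurationError("no barcode channels present")
    bc_names = list(matrix.channel_meta["antigen"].iloc[bc_idx])
    by_code = {frozenset(code): sample for sample, code in scheme.items()}
    for code in scheme.values():
        unknown = set(code) - set(bc_names)
        if unknown:
            raise ConfigurationError(f"scheme references unknown channels {unknown}")

    v = _as_arcsinh(matrix, list(bc_idx))
    lo = v.min(axis=1, keepdims=True)
    hi = v.max(axis=1, keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    r = (v - lo) / span
    order = np.argsort(r, axis=1)[:, ::-1]
    sorted_r = np.take_along_axis(r, order, axis=1)
    sep = (sorted_r[:, k - 1] - sorted_r[:, k]) if k < r.shape[1] else \
        sorted_r[:, k - 1]
    labels = np.full(matrix.n_events, "unassigned", dtype=object)
    top = order[:, :k]
    for i in range(matrix.n_events):
        if sep[i] < separation_cutoff:
            continue
        code = frozenset(bc_names[j] for j in top[i])
        labels[i] = by_code.get(code, "unassigned")
    n = max(matrix.n_events, 1)
    yields = {s: float((labels == s).mean()) for s in scheme}
    yields["unassigned"] = float((labels == "unassigned").mean())
    return BarcodeAssignment(labels, np.maximum(sep, 0.0), yields)
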