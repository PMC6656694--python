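"""FCS 3.0/3.1 reading and writing and the in-memory event table.

The dialect handled here is the one mass cytometers produce and the one this
package writes: list mode, a single DATA segment, floating-point values.
Channel names follow the ``Metal_Target`` convention (e.g. ``89Y_CD45``,
``191Ir_DNA1``); the stain name ($PnS) carries the plain target name.
Values are held as float64 internally regardless of the on-disk type so that
downstream transforms and percentile statistics are numerically stable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FCSFormatError, ScaleError
from .panel import PanelDefinition

SCALES = ("raw", "arcsinh", "arcsinh_p995")

_METAL_RE = re.compile(r"^(\d{1,3}[A-Z][a-z]?)_(.+)$")

#: roles inferred from channel target names written by this package
_ROLE_BY_NAME = {"DNA1": "dna", "DNA2": "dna", "Cisplatin": "viability",
                 "Event_length": "event_length", "Bead": "bead"}


def channel_meta_from_panel(panel: PanelDefinition) -> pd.DataFrame:
    """Channel table (antibodies in panel order, then auxiliary channels)."""
    rows = [
        {"name": f"{c.metal_label}_{c.antigen}", "antigen": c.antigen,
         "metal": c.metal_label, "role": "antibody"}
        for c in panel.channels
    ]
    for a in panel.auxiliary_channels:
        name = f"{a.metal_label}_{a.name}" if a.metal_label else a.name
        rows.append({"name": name, "antigen": a.name, "metal": a.metal_label,
                     "role": a.role})
    return pd.DataFrame(rows)


@dataclass
class EventMatrix:
    """Events x channels intensity table with acquisition time.

    ``scale`` tracks where the data sit in the transform chain
    raw -> arcsinh -> arcsinh_p995; transform operations enforce the order.
    """

    values: np.ndarray
    channel_meta: pd.DataFrame
    time: np.ndarray
    scale: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.time = np.asarray(self.time, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (events x channels)")
        if len(self.channel_meta) != self.values.shape[1]:
            raise ValueError("channel_meta length must equal number of columns")
        if self.time.shape[0] != self.values.shape[0]:
            raise ValueError("time length must equal number of events")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale '{self.scale}'")
        if self.time.size and np.any(np.diff(self.time) < 0):
            raise ValueError("time must be sorted ascending")

    # -- introspection ------------------------------------------------------
    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def column_index(self, antigen: str | None = None, metal: str | None = None) -> int:
        """Column lookup; metal takes precedence over antigen name."""
        meta = self.channel_meta
        if metal is not None:
            hits = np.flatnonzero((meta["metal"] == metal).to_numpy())
            if hits.size:
                return int(hits[0])
        if antigen is not None:
            hits = np.flatnonzero((meta["antigen"] == antigen).to_numpy())
            if hits.size:
                return int(hits[0])
        raise KeyError(f"channel not found (antigen={antigen!r}, metal={metal!r})")

    def get(self, antigen: str) -> np.ndarray:
        return self.values[:, self.column_index(antigen=antigen)]

    def indices_by_role(self, *roles: str) -> np.ndarray:
        return np.flatnonzero(self.channel_meta["role"].isin(roles).to_numpy())

    def antigen_indices(self, antigens: list[str]) -> np.ndarray:
        return np.array([self.column_index(antigen=a) for a in antigens], dtype=int)

    # -- construction helpers -----------------------------------------------
    def with_values(self, values: np.ndarray, scale: str | None = None) -> "EventMatrix":
        return EventMatrix(values, self.channel_meta.copy(), self.time.copy(),
                           scale if scale is not None else self.scale)

    def subset(self, mask: np.ndarray) -> "EventMatrix":
        return EventMatrix(self.values[mask], self.channel_meta.copy(),
                           self.time[mask], self.scale)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.channel_meta["name"]))
        df["Time"] = self.time
        return df


def _infer_role(antigen: str) -> str:
    if antigen in _ROLE_BY_NAME:
        return _ROLE_BY_NAME[antigen]
    if antigen.startswith("BC"):
        return "barcode"
    return "antibody"


# ---------------------------------------------------------------------------
# writing

def write_fcs(matrix: EventMatrix, path) -> None:
    """Write a raw-scale event matrix as FCS 3.1 (float32, little-endian).

    Transformed matrices are refused: they must not masquerade as instrument
    output.
    """
    if matrix.scale != "raw":
        raise ScaleError(f"write_fcs requires raw-scale data, got '{matrix.scale}'")
    names = list(matrix.channel_meta["name"]) + ["Time"]
    stains = list(matrix.channel_meta["antigen"]) + ["Time"]
    data = np.column_stack([matrix.values, matrix.time]) if matrix.n_events else \
        np.empty((0, len(names)))
    n_events, n_par = (data.shape if data.size else (0, len(names)))
    payload = np.ascontiguousarray(data, dtype="<f4").tobytes()

    kw: list[tuple[str, str]] = [
        ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
        ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
        ("$BEGINDATA", "%012d"), ("$ENDDATA", "%012d"),
        ("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "F"), ("$MODE", "L"),
        ("$NEXTDATA", "0"), ("$PAR", str(len(names))), ("$TOT", str(n_events)),
    ]
    for i, (nm, st) in enumerate(zip(names, stains), start=1):
        kw += [(f"$P{i}N", nm), (f"$P{i}S", st), (f"$P{i}B", "32"),
               (f"$P{i}E", "0,0"), (f"$P{i}R", "262144")]

    delim = "/"
    for key, val in kw:
        if delim in key or (val not in ("%012d",) and delim in val):
            raise FCSFormatError(f"keyword contains delimiter: {key}={val}")

    def render(begin: int, end: int) -> bytes:
        parts = [delim]
        for key, val in kw:
            if key == "$BEGINDATA":
                val = "%012d" % begin
            elif key == "$ENDDATA":
                val = "%012d" % end
            parts += [key, delim, val, delim]
        return "".join(parts).encode("latin-1")

    text_start = 58
    text = render(0, 0)
    data_begin = text_start + len(text)
    data_end = data_begin + max(len(payload) - 1, 0)
    text = render(data_begin, data_end)
    assert len(text) == data_begin - text_start

    header = b"FCS3.1    "
    header += f"{text_start:>8d}".encode()
    header += f"{text_start + len(text) - 1:>8d}".encode()
    header += b"       0" * 4  # data/analysis offsets live in TEXT
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


# ---------------------------------------------------------------------------
# reading

def _parse_text_segment(blob: bytes) -> dict[str, str]:
    delim = blob[:1].decode("latin-1")
    fields = blob.decode("latin-1").split(delim)[1:]
    if len(fields) % 2:
        fields = fields[:-1]
    return {fields[i].strip(): fields[i + 1] for i in range(0, len(fields), 2)}


def read_fcs(path) -> EventMatrix:
    """Read an FCS 3.0/3.1 file into a raw-scale :class:`EventMatrix`.

    A ``Time`` channel, when present, populates the per-event acquisition
    time and is removed from the value columns; otherwise time falls back to
    the event index.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58:
        raise FCSFormatError("file too short for an FCS header")
    version = blob[:6].decode("latin-1", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FCSFormatError(f"unsupported FCS version '{version}'")
    try:
        text_begin = int(blob[10:18])
        text_end = int(blob[18:26])
    except ValueError as exc:
        raise FCSFormatError("malformed header offsets") from exc
    text = _parse_text_segment(blob[text_begin:text_end + 1])

    try:
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text["$DATATYPE"]
        byteord = text["$BYTEORD"]
    except KeyError as exc:
        raise FCSFormatError(f"missing required keyword {exc}") from exc
    names = []
    for i in range(1, n_par + 1):
        if f"$P{i}N" not in text:
            raise FCSFormatError(
                f"$PAR={n_par} but $P{i}N missing ($PAR mismatch)")
        names.append(text[f"$P{i}N"])
    stains = [text.get(f"$P{i}S", names[i - 1]) for i in range(1, n_par + 1)]

    if datatype == "F":
        itemsize, code = 4, "f4"
    elif datatype == "D":
        itemsize, code = 8, "f8"
    else:
        raise FCSFormatError(f"unsupported $DATATYPE '{datatype}'")
    if byteord.startswith("1"):
        dtype = "<" + code
    elif byteord.startswith("4"):
        dtype = ">" + code
    else:
        raise FCSFormatError(f"unsupported $BYTEORD '{byteord}'")

    data_begin = int(text.get("$BEGINDATA", 0)) or int(blob[26:34] or 0)
    expected = n_par * n_tot * itemsize
    segment = blob[data_begin:data_begin + expected]
    if len(segment) < expected:
        raise FCSFormatError(
            f"truncated DATA segment: expected {expected} bytes, "
            f"found {len(segment)}")
    values = (np.frombuffer(segment, dtype=dtype).astype(np.float64)
              .reshape(n_tot, n_par)) if expected else np.empty((0, n_par))

    time_cols = [i for i, nm in enumerate(names) if nm.lower() == "time"]
    if time_cols:
        tcol = time_cols[0]
        time = values[:, tcol] if n_tot else np.empty(0)
        keep = [i for i in range(n_par) if i != tcol]
    else:
        time = np.arange(n_tot, dtype=np.float64)
        keep = list(range(n_par))

    rows = []
    for i in keep:
        m = _METAL_RE.match(names[i])
        metal, target = (m.group(1), m.group(2)) if m else ("", names[i])
        rows.append({"name": names[i], "antigen": stains[i] if stains[i] else target,
                     "metal": metal, "role": _infer_role(target)})
    meta = pd.DataFrame(rows, columns=["name", "antigen", "metal", "role"])
    order = np.argsort(time, kind="stable") if n_tot else slice(None)
    return EventMatrix(values[:, keep][order] if n_tot else values[:, keep],
                       meta, time[order] if n_tot else time, scale="raw")
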