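"""Reference antibody panel and lineage (marker-sign) definitions.

The packaged reference panel is a 33-antibody mass-cytometry panel covering
all major peripheral immune lineages plus activation and checkpoint targets,
together with the auxiliary (non-antibody) channels an instrument records:
two iridium DNA intercalators, cisplatin viability, event length, the
cerium-140 calibration-bead channel and six palladium barcoding channels.

Lineage definitions are sign profiles (which antigens a population is
positive/negative for, with graded ``high``/``low`` levels against a
secondary cutoff) arranged in a tree rooted at CD45+ leukocytes.  They drive
both the sequential gating tree and the automatic annotation of clusters.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

CATEGORIES = {"lineage", "subset", "activation", "checkpoint", "exclusion"}
COMPARTMENTS = {"surface", "intracellular"}
LEVELS_POSITIVE = {"pos", "high"}
LEVELS_NEGATIVE = {"neg", "low"}

#: Name of the root of every packaged lineage tree.
ROOT_POPULATION = "CD45+ leukocytes"

LINEAGE_PROFILES = ("pbmc_core", "bmt_subsets")


@dataclass(frozen=True)
class AntibodyChannel:
    metal_label: str
    antigen: str
    clone: str
    category: str
    compartment: str


@dataclass(frozen=True)
class AuxiliaryChannel:
    name: str
    metal_label: str  # empty string for non-mass channels (event length)
    role: str  # dna | viability | event_length | bead | barcode


@dataclass
class PanelDefinition:
    name: str
    channels: list[AntibodyChannel]
    auxiliary_channels: list[AuxiliaryChannel] = field(default_factory=list)

    @property
    def antigens(self) -> list[str]:
        return [c.antigen for c in self.channels]

    @property
    def metals(self) -> list[str]:
        return [c.metal_label for c in self.channels]

    def channel_by_antigen(self, antigen: str) -> AntibodyChannel:
        for c in self.channels:
            if c.antigen == antigen:
                return c
        raise KeyError(antigen)

    def antigens_by_category(self, *categories: str) -> list[str]:
        return [c.antigen for c in self.channels if c.category in categories]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "channels": [vars(c) | {} for c in self.channels],
            "auxiliary_channels": [vars(a) | {} for a in self.auxiliary_channels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelDefinition":
        try:
            return cls(
                name=d["name"],
                channels=[AntibodyChannel(**c) for c in d["channels"]],
                auxiliary_channels=[
                    AuxiliaryChannel(**a) for a in d.get("auxiliary_channels", [])
                ],
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed panel definition: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PanelDefinition":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class LineageDefinition:
    """Marker-sign profile of one population.

    ``positive`` holds (antigen, level) pairs with level in {pos, high},
    ``negative`` with level in {neg, low}.  ``high``/``low`` are judged
    against the per-antigen secondary cutoff, ``pos``/``neg`` against the
    primary cutoff.
    """

    name: str
    parent: str | None
    positive: list[tuple[str, str]] = field(default_factory=list)
    negative: list[tuple[str, str]] = field(default_factory=list)
    ignored: list[str] = field(default_factory=list)

    @property
    def clauses(self) -> list[tuple[str, str]]:
        """All (antigen, relation) clauses; relation in {pos, high, neg, low}."""
        return list(self.positive) + list(self.negative)

    @property
    def antigens(self) -> set[str]:
        return {a for a, _ in self.clauses}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "parent": self.parent,
            "positive": [list(p) for p in self.positive],
            "negative": [list(p) for p in self.negative],
            "ignored": list(self.ignored),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LineageDefinition":
        return cls(
            name=d["name"],
            parent=d.get("parent"),
            positive=[tuple(p) for p in d.get("positive", [])],
            negative=[tuple(p) for p in d.get("negative", [])],
            ignored=list(d.get("ignored", [])),
        )


# ---------------------------------------------------------------------------
# packaged data


def _read_packaged(filename: str) -> str:
    try:
        ref = importlib.resources.files("cytomon.data").joinpath(filename)
        return ref.read_text()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise ConfigurationError(f"packaged data file '{filename}' missing") from exc


def load_reference_panel() -> PanelDefinition:
    """Load the packaged 33-antibody reference panel (plus auxiliary channels)."""
    panel = PanelDefinition.from_yaml(_read_packaged("reference_panel.yaml"))
    if len(panel.channels) != 33:
        raise ConfigurationError(
            f"packaged reference panel corrupted: expected 33 antibody channels, "
            f"found {len(panel.channels)}"
        )
    return panel


def load_lineage_table(profile: str) -> list[LineageDefinition]:
    """Load a packaged lineage profile (``pbmc_core`` or ``bmt_subsets``)."""
    if profile not in LINEAGE_PROFILES:
        raise ConfigurationError(
            f"unknown lineage profile '{profile}'; available: "
            + ", ".join(LINEAGE_PROFILES)
        )
    raw = yaml.safe_load(_read_packaged(f"lineages_{profile}.yaml"))
    return [LineageDefinition.from_dict(d) for d in raw["populations"]]


# ---------------------------------------------------------------------------
# tree helpers


def lineage_map(lineages: list[LineageDefinition]) -> dict[str, LineageDefinition]:
    return {ld.name: ld for ld in lineages}


def children_map(lineages: list[LineageDefinition]) -> dict[str, list[LineageDefinition]]:
    out: dict[str, list[LineageDefinition]] = {ld.name: [] for ld in lineages}
    for ld in lineages:
        if ld.parent is not None:
            out.setdefault(ld.parent, []).append(ld)
    return out

def ancestors(name: str, lineages: list[LineageDefinition]) -> list[str]:
    """Names of ancestors from the immediate parent up to the root."""
    by_name = lineage_map(lineages)
    out = []
    node = by_name.get(name)
    seen = set()
    while node is not None and node.parent is not None:
        if node.parent in seen:  # cycle guard; validate_panel reports it
            break
        seen.add(node.parent)
        out.append(node.parent)
        node = by_name.get(node.parent)
    return out


def subtree(name: str, lineages: list[LineageDefinition]) -> list[str]:
    """Names of ``name`` and all of its descendants (pre-order)."""
    kids = children_map(lineages)
    out = []
    stack = [name]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(c.name for c in reversed(kids.get(node, [])))
    return out


def leaves(lineages: list[LineageDefinition]) -> list[str]:
    kids = children_map(lineages)
    return [ld.name for ld in lineages if not kids.get(ld.name)]


def depth(name: str, lineages: list[LineageDefinition]) -> int:
    return len(ancestors(name, lineages))


# ---------------------------------------------------------------------------
# validation


def validate_panel(
    panel: PanelDefinition, lineages: list[LineageDefinition] | None = None
) -> list[dict]:
    """Check panel and lineage invariants; violations are data, not exceptions.

    Returns a list of records ``{"kind": ..., "detail": ...}``; empty iff all
    invariants hold.
    """
    v: list[dict] = []

    def add(kind: str, detail: str):
        v.append({"kind": kind, "detail": detail})

    metals = [c.metal_label for c in panel.channels]
    for m in sorted({m for m in metals if metals.count(m) > 1}):
        add("metal_collision", f"metal '{m}' used by more than one antibody channel")
    ags = [c.antigen for c in panel.channels]
    for a in sorted({a for a in ags if ags.count(a) > 1}):
        add("antigen_collision", f"antigen '{a}' duplicated in panel")
    for c in panel.channels:
        if c.category not in CATEGORIES:
            add("bad_category", f"{c.antigen}: category '{c.category}'")
        if c.compartment not in COMPARTMENTS:
            add("bad_compartment", f"{c.antigen}: compartment '{c.compartment}'")
    aux_metals = {a.metal_label for a in panel.auxiliary_channels if a.metal_label}
    overlap = aux_metals & set(metals)
    for m in sorted(overlap):
        add("aux_overlap", f"auxiliary channel shares metal '{m}' with an antibody")

    if lineages is None:
        return v

    by_name = lineage_map(lineages)
    panel_ags = set(panel.antigens)
    roots = [ld for ld in lineages if ld.parent is None]
    if len(roots) != 1 or (roots and roots[0].name != ROOT_POPULATION):
        add("bad_root", f"lineage tree must have single root '{ROOT_POPULATION}'")
    for ld in lineages:
        if ld.parent is not None and ld.parent not in by_name:
            add("unknown_parent", f"{ld.name}: parent '{ld.parent}' undefined")
        for a in ld.antigens | set(ld.ignored):
            if a not in panel_ags:
                add("unknown_antigen", f"{ld.name}: antigen '{a}' not in panel")
        for a, lvl in ld.positive:
            if lvl not in LEVELS_POSITIVE:
                add("bad_level", f"{ld.name}: positive level '{lvl}' for {a}")
        for a, lvl in ld.negative:
            if lvl not in LEVELS_NEGATIVE:
                add("bad_level", f"{ld.name}: negative level '{lvl}' for {a}")
        # cycle detection via bounded ancestor walk
        if ld.parent is not None:
            anc, node, hops = set(), ld, 0
            while node is not None and node.parent is not None:
                if node.parent == ld.name or hops > len(lineages):
                    add("cycle", f"{ld.name} participates in a parent cycle")
                    break
                node = by_name.get(node.parent)
                hops += 1
    # sibling separability: each pair of siblings differs in >=1 (antigen, sign)
    kids = children_map(lineages)
    for parent, cs in kids.items():
        for i in range(len(cs)):
            for j in range(i + 1, len(cs)):
                a, b = cs[i], cs[j]
                if set(a.clauses) == set(b.clauses):
                    add(
                        "inseparable_siblings",
                        f"'{a.name}' and '{b.name}' (children of '{parent}') share "
                        "identical marker-sign profiles",
                    )
    return v
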