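"""Core domain types for regulatory-network extension.

A *RegIN* (regulatory interaction network) is a named, versioned directed
network of regulator -> target interactions (miRNA-target, TF-target,
drug-target, ...) whose nodes each carry identifiers in one or more
identifier systems (Ensembl gene, miRBase accession, DrugBank, ...).
A *seed network* is the user's starting network; extension grafts onto it
every RegIN interaction in which a seed node participates, keeping one
provenance-tagged edge per supporting RegIN.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

#: Attribute names reserved by the extension process.  A seed network that
#: already carries them was produced by a previous run and is refused as
#: input to prevent double-grafting (see linker module).
ORIGIN_ATTR = "reglink::origin"
REGIN_ATTR = "reglink::regin"
VISIBLE_ATTR = "reglink::visible"
STYLE_ATTR = "reglink::style"
CANONICAL_ATTR = "reglink::canonical"

ORIGIN_INITIAL = "initial"
ORIGIN_ADDED = "added"

STYLE_INITIAL = "grey circle"
STYLE_ADDED = "pink hexagon"

#: Default system priority used to pick a node's canonical identifier.
#: Mirrors the per-biotype unifying systems commonly used when building
#: RegINs: Ensembl gene ids for genes, miRBase accessions for miRNAs,
#: DrugBank ids for drugs, with NCBI gene / UniProt / miRBase ids as the
#: secondary systems RegINs also embed.
DEFAULT_CANONICAL_PRIORITY = (
    "ensembl",
    "miRBase-accession",
    "drugbank",
    "ncbigene",
    "uniprot",
    "miRBase-id",
)

UNKNOWN_SYSTEM = "unknown"


class Biotype(str, enum.Enum):
    gene = "gene"
    protein = "protein"
    microRNA = "microRNA"
    drug = "drug"
    other = "other"

    @classmethod
    def coerce(cls, value: str | "Biotype") -> "Biotype":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            return cls.other


@dataclass(frozen=True)
class IdentifierSet:
    """A set of (system, value) identifier pairs attached to one molecule.

    Values are compared verbatim: identifier matching is exact and
    case-sensitive (case folding could merge distinct miRBase ids such as
    ``hsa-miR-93`` vs ``hsa-mir-93``).  ``system`` may be ``"unknown"`` for
    bare identifiers of unstated provenance.
    """

    entries: frozenset[tuple[str, str]]

    def __init__(self, entries: Iterable[tuple[str, str]] = ()):
        frozen = frozenset((str(s), str(v)) for s, v in entries)
        for system, value in frozen:
            if not value:
                raise ValueError("identifier values must be non-empty")
        object.__setattr__(self, "entries", frozen)

    def values(self) -> frozenset[str]:
        """All identifier value strings, ignoring the system."""
        return frozenset(v for _, v in self.entries)

    def by_system(self, system: str) -> frozenset[str]:
        return frozenset(v for s, v in self.entries if s == system)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def parse(cls, raw: Iterable[str]) -> "IdentifierSet":
        """Parse ``"system:value"`` strings; a bare value gets system
        ``"unknown"``.  Only the first colon splits, so values containing
        colons survive."""
        entries = []
        for item in raw:
            item = str(item)
            if not item:
                continue
            if ":" in item:
                system, value = item.split(":", 1)
                if not system:
                    system = UNKNOWN_SYSTEM
            else:
                system, value = UNKNOWN_SYSTEM, item
            if value:
                entries.append((system, value))
        return cls(entries)

    def encode(self) -> list[str]:
        """Deterministic ``"system:value"`` encoding (sorted)."""
        return [f"{s}:{v}" for s, v in sorted(self.entries)]


@dataclass
class RegINNode:
    """One biomolecule in a RegIN: a regulator or a target."""

    node_id: str
    label: str
    identifiers: IdentifierSet
    biotype: Biotype = Biotype.other
    extra: dict[str, str] = field(default_factory=dict)


@dataclass
class RegulatoryInteraction:
    """One directed regulator -> target interaction.

    ``evidence`` maps attribute names (e.g. ``"pmid"``, ``"score"``) to
    lists of strings; duplicate (source, target) rows within one RegIN are
    collapsed at load time with their evidence concatenated.
    """

    source_id: str
    target_id: str
    interaction_type: str = ""
    evidence: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class RegIN:
    """A named, versioned directed regulatory interaction network."""

    name: str
    database: str = "unknown"
    version: str = "unknown"
    organism: str = "unknown"
    interaction_type: str = "unknown"
    nodes: dict[str, RegINNode] = field(default_factory=dict)
    interactions: list[RegulatoryInteraction] = field(default_factory=list)

    def add_node(self, node: RegINNode) -> None:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id!r} in RegIN {self.name!r}")
        self.nodes[node.node_id] = node

    def validate_refs(self) -> None:
        for it in self.interactions:
            for nid in (it.source_id, it.target_id):
                if nid not in self.nodes:
                    raise ValueError(
                        f"interaction references undeclared node {nid!r} in RegIN {self.name!r}"
                    )


@dataclass
class SeedNetwork:
    """The user's initial network plus the node attribute used for matching.

    ``nodes`` maps node id -> attribute dict; attribute values are strings
    or lists of strings.  ``id_attribute`` names the attribute whose values
    are compared against RegIN node identifiers.
    """

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: list[tuple[str, str, dict]] = field(default_factory=list)
    id_attribute: str = "id"
    directed: bool = False
    label: str = "seed"

    def id_values(self, node_id: str) -> list[str]:
        """The matching values of one node (scalar attributes wrapped)."""
        raw = self.nodes[node_id].get(self.id_attribute)
        if raw is None:
            return []
        if isinstance(raw, (list, tuple)):
            return [str(v) for v in raw if str(v)]
        return [str(raw)] if str(raw) else []

    def has_id_attribute(self) -> bool:
        return any(self.id_attribute in attrs for attrs in self.nodes.values())


@dataclass
class LinkReport:
    """Per-RegIN extension counts plus matching diagnostics."""

    per_regin: dict[str, dict[str, int]] = field(default_factory=dict)
    diagnostics: list[str] = field(default_factory=list)

    def total_added_interactions(self) -> int:
        return sum(c["added_interactions"] for c in self.per_regin.values())

    def total_added_nodes(self) -> int:
        return sum(c["added_nodes"] for c in self.per_regin.values())

    def to_dict(self) -> dict:
        return {
            "per_regin": self.per_regin,
            "totals": {
                "added_interactions": self.total_added_interactions(),
                "added_nodes": self.total_added_nodes(),
            },
            "diagnostics": list(self.diagnostics),
        }


@dataclass
class ExtendedNetwork:
    """Seed network plus grafted regulatory interactions.

    Backed by a :class:`networkx.MultiDiGraph`: an interaction supported by
    k RegINs appears as k parallel edges, each tagged with exactly one RegIN
    name.  Filtering state (per-RegIN visibility, overlap threshold) is held
    on the object and applied non-destructively as per-element visibility
    flags, so hide/show and threshold can be applied and restored without
    losing anything.
    """

    graph: nx.MultiDiGraph
    regin_names: list[str] = field(default_factory=list)
    visibility: dict[str, bool] = field(default_factory=dict)
    threshold: int = 1
    id_attribute: str = "id"
    seed_directed: bool = False
    label: str = "extended"

    def added_edges(self) -> list[tuple[str, str, int, dict]]:
        return [
            (u, v, k, d)
            for u, v, k, d in self.graph.edges(keys=True, data=True)
            if d.get(ORIGIN_ATTR) == ORIGIN_ADDED
        ]

    def seed_edges(self) -> list[tuple[str, str, int, dict]]:
        return [
            (u, v, k, d)
            for u, v, k, d in self.graph.edges(keys=True, data=True)
            if d.get(ORIGIN_ATTR) == ORIGIN_INITIAL
        ]

    def added_nodes(self) -> list[str]:
        return [
            n
            for n, d in self.graph.nodes(data=True)
            if d.get(ORIGIN_ATTR) == ORIGIN_ADDED
        ]

    def seed_nodes(self) -> list[str]:
        return [
            n
            for n, d in self.graph.nodes(data=True)
            if d.get(ORIGIN_ATTR) == ORIGIN_INITIAL
        ]

    def visible_added_edges(self) -> list[tuple[str, str, int, dict]]:
        return [
            (u, v, k, d)
            for u, v, k, d in self.added_edges()
            if d.get(VISIBLE_ATTR, "true") == "true"
        ]

    def node_canonical(self, node_id: str) -> str:
        """Canonical endpoint key used for support grouping."""
        return self.graph.nodes[node_id].get(CANONICAL_ATTR, node_id)


def canonical_key(
    node,
    priority: Iterable[str] = DEFAULT_CANONICAL_PRIORITY,
) -> str:
    """The single identifier that defines a node's identity during merging.

    Returns the value of the first identifier whose system appears earliest
    in ``priority``; when no system matches, the lexicographically smallest
    identifier value.  Deterministic for fixed input, so two nodes with
    identical identifier sets always merge.

    ``node`` is a :class:`RegINNode` or anything with an ``identifiers``
    :class:`IdentifierSet`; an :class:`IdentifierSet` itself is accepted.

    Raises ``ValueError`` for an identifier-less node.
    """
    idset = node if isinstance(node, IdentifierSet) else node.identifiers
    if not idset:
        raise ValueError("no identifiers")
    for system in priority:
        values = idset.by_system(system)
        if values:
            return min(values)
    return min(idset.values())
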