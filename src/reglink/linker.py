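"""The extension algorithm: graft qualifying RegIN interactions onto a seed.

A RegIN interaction qualifies when a seed node participates in it — as the
regulator when adding targets, as the target when adding regulators
("add regulators" means look for interactions that target the seed nodes),
or as either under the default ``both``.  Each qualifying interaction
contributes exactly one added edge per supporting RegIN, so an interaction
present in k RegINs becomes k parallel edges, each carrying a single RegIN
provenance tag.  Extension is one-hop: only the original seed nodes are
queried, added nodes are never re-expanded (re-run with the output as the
seed for transitive extension).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .graph_model import (
    CANONICAL_ATTR,
    DEFAULT_CANONICAL_PRIORITY,
    ORIGIN_ADDED,
    ORIGIN_ATTR,
    ORIGIN_INITIAL,
    REGIN_ATTR,
    STYLE_ADDED,
    STYLE_ATTR,
    STYLE_INITIAL,
    VISIBLE_ATTR,
    ExtendedNetwork,
    LinkReport,
    RegIN,
    RegINNode,
    SeedNetwork,
    canonical_key,
)

INTRODUCED_BY_ATTR = "reglink::introduced-by"

DIRECTIONS = ("targets", "regulators", "both")


@dataclass
class LinkConfig:
    """Run configuration for one extension pass."""

    regins: list[RegIN] = field(default_factory=list)
    direction: str = "both"
    #: matching attribute; None means use the seed network's own
    id_attribute: str | None = None
    canonical_priority: tuple[str, ...] = DEFAULT_CANONICAL_PRIORITY
    #: "canonical" merges added nodes across RegINs when their canonical
    #: keys are equal (deterministic and transitive); "any-shared-id"
    #: additionally merges nodes sharing any identifier value.
    merge: str = "canonical"

    def validate(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        names = [r.name for r in self.regins]
        if len(set(names)) != len(names):
            raise ValueError(f"RegIN names must be pairwise distinct: {names}")
        if self.merge not in ("canonical", "any-shared-id"):
            raise ValueError(f"merge must be 'canonical' or 'any-shared-id', got {self.merge!r}")


def index_regin(regin: RegIN) -> tuple[dict[str, set[str]], list[str]]:
    """Identifier value -> node ids carrying it, for O(1) expected lookup.

    Returns (index, notes); a note is emitted for every value shared by
    more than one node (ambiguous lookups take the union of hits).
    """
    index: dict[str, set[str]] = {}
    notes: list[str] = []
    for node in regin.nodes.values():
        for value in node.identifiers.values():
            index.setdefault(value, set()).add(node.node_id)
    for value, ids in index.items():
        if len(ids) > 1:
            notes.append(
                f"RegIN {regin.name!r}: identifier {value!r} is carried by "
                f"{len(ids)} nodes ({', '.join(sorted(ids))})"
            )
    return index, notes


def match_seed(
    seed: SeedNetwork, regin: RegIN, id_attribute: str | None = None
) -> dict[str, set[str]]:
    """Seed node id -> RegIN node ids it matches.

    A seed node matches a RegIN node iff any of its id-attribute values
    equals, exactly and case-sensitively, any identifier value of the RegIN
    node.  Seed nodes lacking the attribute match nothing.
    """
    if id_attribute is not None and id_attribute != seed.id_attribute:
        seed = SeedNetwork(
            nodes=seed.nodes,
            edges=seed.edges,
            id_attribute=id_attribute,
            directed=seed.directed,
            label=seed.label,
        )
    index, _ = index_regin(regin)
    matches: dict[str, set[str]] = {}
    for node_id in seed.nodes:
        hits: set[str] = set()
        for value in seed.id_values(node_id):
            hits |= index.get(value, set())
        if hits:
            matches[node_id] = hits
    return matches


def _seed_already_extended(seed: SeedNetwork) -> bool:
    for attrs in seed.nodes.values():
        if ORIGIN_ATTR in attrs or REGIN_ATTR in attrs:
            return True
    for _, _, attrs in seed.edges:
        if ORIGIN_ATTR in attrs or REGIN_ATTR in attrs:
            return True
    return False


class _AddedNodePool:
    """Merges non-seed endpoints across RegINs into shared added nodes."""

    def __init__(self, graph: nx.MultiDiGraph, priority, merge: str):
        self.graph = graph
        self.priority = priority
        self.merge = merge
        self.by_key: dict[str, str] = {}
        self.by_value: dict[str, str] = {}

    def get(self, node: RegINNode, regin: RegIN, diagnostics: list[str]) -> tuple[str, bool]:
        """Graph node id for this RegIN endpoint; True when newly created."""
        try:
            key = canonical_key(node, self.priority)
        except ValueError:
            key = f"{regin.name}::{node.node_id}"
            diagnostics.append(
                f"RegIN {regin.name!r}: added node {node.node_id!r} has no "
                "identifiers; kept separate under a per-RegIN key"
            )
        if self.merge == "any-shared-id":
            for value in sorted(node.identifiers.values()):
                if value in self.by_value:
                    existing = self.by_value[value]
                    self._absorb(existing, node)
                    return existing, False
        if key in self.by_key:
            existing = self.by_key[key]
            self._absorb(existing, node)
            return existing, False
        graph_id = f"added::{key}"
        self.by_key[key] = graph_id
        self.graph.add_node(
            graph_id,
            label=node.label,
            identifiers=node.identifiers.encode(),
            biotype=node.biotype.value,
            **{
                ORIGIN_ATTR: ORIGIN_ADDED,
                STYLE_ATTR: STYLE_ADDED,
                VISIBLE_ATTR: "true",
                CANONICAL_ATTR: key,
            },
        )
        for value in node.identifiers.values():
            self.by_value.setdefault(value, graph_id)
        return graph_id, True

    def _absorb(self, graph_id: str, node: RegINNode) -> None:
        # same molecule from another RegIN: union the identifier lists
        attrs = self.graph.nodes[graph_id]
        known = set(attrs.get("identifiers", []))
        merged = sorted(known | set(node.identifiers.encode()))
        attrs["identifiers"] = merged
        for value in node.identifiers.values():
            self.by_value.setdefault(value, graph_id)


def extend(seed: SeedNetwork, config: LinkConfig) -> tuple[ExtendedNetwork, LinkReport]:
    """Extend a seed network with qualifying interactions from each RegIN.

    The seed subgraph (nodes, edges, attributes) is contained unmodified in
    the output.  Endpoints matching a seed node attach to that seed node;
    non-matching endpoints become added nodes, merged across RegINs so the
    same molecule appearing in two RegINs is a single node.  A seed network
    that already carries extension provenance attributes is refused: re-
    grafting would double-count support.
    """
    config.validate()
    if _seed_already_extended(seed):
        raise ValueError(
            "seed network already carries extension provenance attributes; "
            "refusing to extend an extended network (re-run on the original "
            "seed, or strip the reglink::* attributes first)"
        )
    id_attribute = config.id_attribute or seed.id_attribute
    report = LinkReport()
    graph = nx.MultiDiGraph()
    for node_id, attrs in seed.nodes.items():
        graph.add_node(
            node_id,
            **attrs,
            **{
                ORIGIN_ATTR: ORIGIN_INITIAL,
                STYLE_ATTR: STYLE_INITIAL,
                VISIBLE_ATTR: "true",
            },
        )
    for u, v, attrs in seed.edges:
        graph.add_edge(
            u, v, **attrs, **{ORIGIN_ATTR: ORIGIN_INITIAL, VISIBLE_ATTR: "true"}
        )

    extended = ExtendedNetwork(
        graph=graph,
        regin_names=[r.name for r in config.regins],
        visibility={r.name: True for r in config.regins},
        threshold=1,
        id_attribute=id_attribute,
        seed_directed=seed.directed,
        label=f"{seed.label}-extended",
    )

    working = seed
    if id_attribute != seed.id_attribute:
        working = SeedNetwork(
            nodes=seed.nodes,
            edges=seed.edges,
            id_attribute=id_attribute,
            directed=seed.directed,
            label=seed.label,
        )
    if working.nodes and not working.has_id_attribute():
        report.diagnostics.append(
            f"id attribute {id_attribute!r} absent from all seed nodes; "
            "nothing can match"
        )

    pool = _AddedNodePool(graph, config.canonical_priority, config.merge)
    # seed nodes participate in support grouping under their own matching
    # values: canonical endpoint key = the node's smallest id value
    for node_id in working.nodes:
        values = working.id_values(node_id)
        if values:
            graph.nodes[node_id][CANONICAL_ATTR] = min(values)

    for regin in config.regins:
        counts = {"added_interactions": 0, "added_nodes": 0, "matched_seed_nodes": 0}
        _, ambiguity_notes = index_regin(regin)
        report.diagnostics.extend(ambiguity_notes)
        for node in regin.nodes.values():
            if not node.identifiers:
                report.diagnostics.append(
                    f"RegIN {regin.name!r}: node {node.node_id!r} has no "
                    "identifiers and cannot match"
                )
        matches = match_seed(working, regin)
        counts["matched_seed_nodes"] = len(matches)
        for seed_id, hits in matches.items():
            if len(hits) > 1:
                report.diagnostics.append(
                    f"RegIN {regin.name!r}: seed node {seed_id!r} matches "
                    f"{len(hits)} RegIN nodes; taking the union of their interactions"
                )
        reverse: dict[str, list[str]] = {}
        for seed_id, hits in matches.items():
            for regin_node in hits:
                reverse.setdefault(regin_node, []).append(seed_id)
        for attach in reverse.values():
            attach.sort()

        for it in regin.interactions:
            src_seed = reverse.get(it.source_id, [])
            tgt_seed = reverse.get(it.target_id, [])
            if config.direction == "targets":
                qualifies = bool(src_seed)
            elif config.direction == "regulators":
                qualifies = bool(tgt_seed)
            else:
                qualifies = bool(src_seed) or bool(tgt_seed)
            if not qualifies:
                continue
            if src_seed:
                sources = src_seed
            else:
                graph_id, created = pool.get(
                    regin.nodes[it.source_id], regin, report.diagnostics
                )
                if created:
                    graph.nodes[graph_id][INTRODUCED_BY_ATTR] = regin.name
                    counts["added_nodes"] += 1
                sources = [graph_id]
            if tgt_seed:
                targets = tgt_seed
            else:
                graph_id, created = pool.get(
                    regin.nodes[it.target_id], regin, report.diagnostics
                )
                if created:
                    graph.nodes[graph_id][INTRODUCED_BY_ATTR] = regin.name
                    counts["added_nodes"] += 1
                targets = [graph_id]
            for u in sources:
                for v in targets:
                    edge_attrs: dict = {
                        REGIN_ATTR: regin.name,
                        ORIGIN_ATTR: ORIGIN_ADDED,
                        VISIBLE_ATTR: "true",
                        "interaction": it.interaction_type or regin.interaction_type,
                    }
                    for k, vals in sorted(it.evidence.items()):
                        edge_attrs[k] = list(vals)
                    graph.add_edge(u, v, **edge_attrs)
                    counts["added_interactions"] += 1
                    if u == v:
                        report.diagnostics.append(
                            f"RegIN {regin.name!r}: self-loop added on {u!r} "
                            "(autoregulation)"
                        )
        report.per_regin[regin.name] = counts
    return extended, report


def link_stats(extended: ExtendedNetwork) -> LinkReport:
    """Recount per-RegIN added edges and nodes by a full graph scan."""
    report = LinkReport()
    for name in extended.regin_names:
        report.per_regin[name] = {
            "added_interactions": 0,
            "added_nodes": 0,
            "matched_seed_nodes": 0,
        }
    seed_nodes = set(extended.seed_nodes())
    touched: dict[str, set[str]] = {name: set() for name in extended.regin_names}
    for u, v, _k, d in extended.added_edges():
        name = d[REGIN_ATTR]
        counts = report.per_regin.setdefault(
            name, {"added_interactions": 0, "added_nodes": 0, "matched_seed_nodes": 0}
        )
        counts["added_interactions"] += 1
        for endpoint in (u, v):
            if endpoint in seed_nodes:
                touched.setdefault(name, set()).add(endpoint)
    for node in extended.added_nodes():
        name = extended.graph.nodes[node].get(INTRODUCED_BY_ATTR)
        if name in report.per_regin:
            report.per_regin[name]["added_nodes"] += 1
    for name, nodes in touched.items():
        report.per_regin[name]["matched_seed_nodes"] = len(nodes)
    return report


def recover_seed(extended: ExtendedNetwork) -> SeedNetwork:
    """Strip every added element and extension attribute; the exact seed."""
    seed = SeedNetwork(
        id_attribute=extended.id_attribute,
        directed=extended.seed_directed,
        label=extended.label.removesuffix("-extended") or "seed",
    )
    reserved = (ORIGIN_ATTR, STYLE_ATTR, VISIBLE_ATTR, CANONICAL_ATTR, INTRODUCED_BY_ATTR)
    for node in extended.seed_nodes():
        attrs = {
            k: v for k, v in extended.graph.nodes[node].items() if k not in reserved
        }
        seed.nodes[node] = attrs
    for u, v, _k, d in extended.seed_edges():
        attrs = {k: v for k, v in d.items() if k not in reserved}
        seed.edges.append((u, v, attrs))
    return seed
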