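"""Build RegIN files from tabular regulator -> target interaction dumps.

Interaction databases (TargetScan-, miRTarBase-, DrugBank-style exports)
ship as TSV tables with one interaction per row.  A :class:`BuildSchema`
declares which columns hold the source/target labels and identifiers (per
identifier system), which columns become edge evidence, and the RegIN
metadata.  Multi-valued identifier cells use a configurable delimiter
(default ``"|"``).  No licensed data ships with this package — only the
converter; users run it on their own database exports.

Node identity during building is the canonical key, so one molecule listed
under several labels but sharing its primary identifier collapses to a
single node (collisions are diagnosed, not hidden).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .graph_model import (
    Biotype,
    DEFAULT_CANONICAL_PRIORITY,
    IdentifierSet,
    RegIN,
    RegINNode,
    RegulatoryInteraction,
    canonical_key,
)


@dataclass
class BuildSchema:
    """Column-role declaration for one interaction table."""

    source_ids: dict[str, str]  # identifier system -> column name
    target_ids: dict[str, str]
    source_label: str | None = None
    target_label: str | None = None
    source_biotype: str = "other"
    target_biotype: str = "other"
    edge_attributes: list[str] = field(default_factory=list)
    database: str = "unknown"
    version: str = "unknown"
    organism: str = "unknown"
    interaction_type: str = "unknown"
    name: str = "custom"
    list_delimiter: str = "|"
    canonical_priority: tuple[str, ...] = DEFAULT_CANONICAL_PRIORITY

    def __post_init__(self):
        if not self.source_ids or not self.target_ids:
            raise ValueError("schema needs at least one source and one target id column")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BuildSchema":
        with open(path, encoding="utf-8-sig") as fh:
            raw = yaml.safe_load(fh) or {}
        if "canonical_priority" in raw:
            raw["canonical_priority"] = tuple(raw["canonical_priority"])
        return cls(**raw)

    def columns(self) -> list[str]:
        cols = list(self.source_ids.values()) + list(self.target_ids.values())
        for col in (self.source_label, self.target_label):
            if col:
                cols.append(col)
        cols.extend(self.edge_attributes)
        return cols


def _cell_values(cell: str, delimiter: str) -> list[str]:
    return [v.strip() for v in str(cell).split(delimiter) if v.strip()]


def _row_identifiers(row, id_columns: dict[str, str], delimiter: str) -> IdentifierSet:
    entries = []
    for system, column in id_columns.items():
        for value in _cell_values(row[column], delimiter):
            entries.append((system, value))
    return IdentifierSet(entries)


def build_regin(table_path: str | Path, schema: BuildSchema) -> tuple[RegIN, dict]:
    """Convert an interaction TSV into a RegIN; returns (regin, report).

    One node per distinct canonical key on each side (labels and
    identifiers merged across rows), one interaction per distinct
    (source, target) pair with evidence merged.  Rows missing all source
    ids or all target ids are skipped and counted.
    """
    frame = pd.read_csv(
        table_path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8-sig"
    )
    missing = [c for c in schema.columns() if c not in frame.columns]
    if missing:
        raise ValueError(
            f"{table_path}: schema columns missing from table: {', '.join(missing)}"
        )
    report = {
        "rows": int(len(frame)),
        "rows_skipped": 0,
        "duplicates_skipped": 0,
        "label_collisions": 0,
        "warnings": [],
    }
    regin = RegIN(
        name=schema.name,
        database=schema.database,
        version=schema.version,
        organism=schema.organism,
        interaction_type=schema.interaction_type,
    )
    if frame.empty:
        report["warnings"].append(f"{table_path}: empty table, empty RegIN")
        return regin, report

    nodes_by_key: dict[str, RegINNode] = {}
    interactions: dict[tuple[str, str], RegulatoryInteraction] = {}

    def ensure_node(idset: IdentifierSet, label: str, biotype: str) -> str:
        key = canonical_key(idset, schema.canonical_priority)
        node = nodes_by_key.get(key)
        if node is None:
            node = RegINNode(
                node_id=key,
                label=label or key,
                identifiers=idset,
                biotype=Biotype.coerce(biotype),
            )
            nodes_by_key[key] = node
            regin.add_node(node)
        else:
            if label and node.label != label and node.label != key:
                report["label_collisions"] += 1
                report["warnings"].append(
                    f"canonical key {key!r} listed under labels "
                    f"{node.label!r} and {label!r}; keeping {node.label!r}"
                )
            elif label and node.label == key:
                node.label = label
            node.identifiers = IdentifierSet(set(node.identifiers) | set(idset))
        return key

    for _, row in frame.iterrows():
        src_ids = _row_identifiers(row, schema.source_ids, schema.list_delimiter)
        tgt_ids = _row_identifiers(row, schema.target_ids, schema.list_delimiter)
        if not src_ids or not tgt_ids:
            report["rows_skipped"] += 1
            continue
        src_label = str(row[schema.source_label]) if schema.source_label else ""
        tgt_label = str(row[schema.target_label]) if schema.target_label else ""
        src_key = ensure_node(src_ids, src_label, schema.source_biotype)
        tgt_key = ensure_node(tgt_ids, tgt_label, schema.target_biotype)
        evidence = {}
        for column in schema.edge_attributes:
            values = _cell_values(row[column], schema.list_delimiter)
            if values:
                evidence[column] = values
        pair = (src_key, tgt_key)
        if pair in interactions:
            report["duplicates_skipped"] += 1
            existing = interactions[pair]
            for k, vals in evidence.items():
                bucket = existing.evidence.setdefault(k, [])
                bucket.extend(v for v in vals if v not in bucket)
        else:
            interactions[pair] = RegulatoryInteraction(
                source_id=src_key,
                target_id=tgt_key,
                interaction_type=schema.interaction_type,
                evidence=evidence,
            )
    regin.interactions = list(interactions.values())
    return regin, report


def validate_regin(regin: RegIN) -> list[dict]:
    """Quality report before linking; empty iff the RegIN is well-formed.

    Each issue is ``{"level": "warning"|"info", "kind": ..., "detail": ...}``.
    Self-loops are info only: autoregulation is biologically real.
    """
    issues: list[dict] = []

    def issue(level: str, kind: str, detail: str) -> None:
        issues.append({"level": level, "kind": kind, "detail": detail})

    for node in regin.nodes.values():
        if not node.identifiers:
            issue(
                "warning",
                "identifier-less-node",
                f"node {node.node_id!r} has no identifiers and can never match",
            )
    seen: set[tuple[str, str]] = set()
    for it in regin.interactions:
        for nid in (it.source_id, it.target_id):
            if nid not in regin.nodes:
                issue(
                    "warning",
                    "dangling-edge",
                    f"interaction {it.source_id!r} -> {it.target_id!r} references "
                    f"undeclared node {nid!r}",
                )
        pair = (it.source_id, it.target_id)
        if pair in seen:
            issue(
                "warning",
                "duplicate-interaction",
                f"duplicate interaction {pair[0]!r} -> {pair[1]!r}",
            )
        seen.add(pair)
        if it.source_id == it.target_id:
            issue("info", "self-loop", f"self-loop on {it.source_id!r}")
    for field_name in ("database", "version", "organism", "interaction_type"):
        if getattr(regin, field_name) in ("", "unknown"):
            issue("warning", "missing-metadata", f"metadata field {field_name!r} not set")
    return issues
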