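"""Read and write networks in XGMML.

XGMML (eXtensible Graph Markup and Modelling Language) is the XML graph
interchange format RegIN files are stored in.  The dialect used here:

* root element ``graph`` with ``label`` and ``directed`` ("1"/"0");
* attributes as ``att`` elements with ``name``, ``value`` and ``type``
  in {string, integer, real, list}; list members are nested ``att``
  children of type string (order preserved);
* RegIN graph-level metadata keys: ``database``, ``version``,
  ``organism``, ``type``;
* RegIN node identifiers: a single ``identifiers`` list attribute whose
  entries are ``"system:value"`` strings (a bare value means system
  "unknown").

Documents with or without the XGMML XML namespace are accepted; output is
namespace-free.  ``graphics`` subelements are skipped on read and never
written.  Exactly one ``graph`` element per file.
"""

from __future__ import annotations

import codecs
import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .graph_model import (
    Biotype,
    IdentifierSet,
    RegIN,
    RegINNode,
    RegulatoryInteraction,
    SeedNetwork,
)

AttrValue = str | int | float | list


class XgmmlFormatError(ValueError):
    """The file is XML but not a valid XGMML network."""


@dataclass
class XgmmlNode:
    node_id: str
    label: str = ""
    attributes: dict[str, AttrValue] = field(default_factory=dict)


@dataclass
class XgmmlEdge:
    source: str
    target: str
    attributes: dict[str, AttrValue] = field(default_factory=dict)


@dataclass
class XgmmlDocument:
    """In-memory form of one XGMML file."""

    label: str = ""
    directed: bool = False
    attributes: dict[str, AttrValue] = field(default_factory=dict)
    nodes: list[XgmmlNode] = field(default_factory=list)
    edges: list[XgmmlEdge] = field(default_factory=list)

    def node_ids(self) -> set[str]:
        return {n.node_id for n in self.nodes}

    def validate(self) -> None:
        seen: set[str] = set()
        for n in self.nodes:
            if n.node_id in seen:
                raise XgmmlFormatError(f"duplicate node id {n.node_id!r}")
            seen.add(n.node_id)
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in seen:
                    raise XgmmlFormatError(
                        f"edge {e.source!r} -> {e.target!r} references "
                        f"undeclared node {endpoint!r}"
                    )


_TRUE_STRINGS = {"1", "true", "yes"}


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_att(elem: ET.Element) -> tuple[str, AttrValue]:
    name = elem.get("name", "")
    att_type = elem.get("type", "string")
    if att_type == "list":
        members = []
        for child in elem:
            if _localname(child.tag) == "att":
                members.append(child.get("value", ""))
        return name, members
    raw = elem.get("value", "")
    if att_type == "integer":
        return name, int(raw)
    if att_type == "real":
        return name, float(raw)
    return name, raw


def _collect_atts(elem: ET.Element) -> dict[str, AttrValue]:
    attrs: dict[str, AttrValue] = {}
    for child in elem:
        if _localname(child.tag) == "att":
            name, value = _parse_att(child)
            attrs[name] = value
    return attrs


def read_xgmml(path: str | Path) -> XgmmlDocument:
    """Parse one XGMML file into an :class:`XgmmlDocument`.

    Raises ``xml.etree.ElementTree.ParseError`` (with line/column) for
    malformed XML and :class:`XgmmlFormatError` for structural problems
    (wrong root, duplicate node ids, dangling edges, multiple graphs).
    """
    path = Path(path)
    tree = ET.parse(path)
    root = tree.getroot()
    if _localname(root.tag) != "graph":
        raise XgmmlFormatError(
            f"{path}: root element is {_localname(root.tag)!r}, expected 'graph'"
        )
    if any(_localname(c.tag) == "graph" for c in root.iter() if c is not root):
        raise XgmmlFormatError(f"{path}: multiple graph elements (one network per file)")

    doc = XgmmlDocument(
        label=root.get("label", ""),
        directed=str(root.get("directed", "0")).lower() in _TRUE_STRINGS,
        attributes=_collect_atts(root),
    )
    for child in root:
        tag = _localname(child.tag)
        if tag == "node":
            node_id = child.get("id")
            if node_id is None:
                raise XgmmlFormatError(f"{path}: node without id attribute")
            doc.nodes.append(
                XgmmlNode(
                    node_id=node_id,
                    label=child.get("label", node_id),
                    attributes=_collect_atts(child),
                )
            )
        elif tag == "edge":
            source, target = child.get("source"), child.get("target")
            if source is None or target is None:
                raise XgmmlFormatError(f"{path}: edge missing source/target")
            doc.edges.append(
                XgmmlEdge(source=source, target=target, attributes=_collect_atts(child))
            )
        # att handled above; graphics and anything else skipped
    doc.validate()
    return doc


def _att_element(name: str, value: AttrValue) -> ET.Element:
    if isinstance(value, list):
        elem = ET.Element("att", {"name": name, "type": "list"})
        for member in value:
            ET.SubElement(
                elem, "att", {"name": name, "value": str(member), "type": "string"}
            )
        return elem
    if isinstance(value, bool):  # bool before int: bool subclasses int
        att_type, text = "string", str(value).lower()
    elif isinstance(value, int):
        att_type, text = "integer", str(value)
    elif isinstance(value, float):
        att_type, text = "real", repr(value)
    else:
        att_type, text = "string", str(value)
    return ET.Element("att", {"name": name, "value": text, "type": att_type})


def write_xgmml(doc: XgmmlDocument, path: str | Path) -> None:
    """Serialise a document as UTF-8 XGMML.

    Nodes are written before edges, both in insertion order, and attribute
    emission is deterministic, so writing the same document twice yields
    byte-identical files.
    """
    doc.validate()
    root = ET.Element(
        "graph", {"label": doc.label, "directed": "1" if doc.directed else "0"}
    )
    for name, value in doc.attributes.items():
        root.append(_att_element(name, value))
    for node in doc.nodes:
        elem = ET.SubElement(root, "node", {"id": node.node_id, "label": node.label})
        for name, value in node.attributes.items():
            elem.append(_att_element(name, value))
    for edge in doc.edges:
        elem = ET.SubElement(root, "edge", {"source": edge.source, "target": edge.target})
        for name, value in edge.attributes.items():
            elem.append(_att_element(name, value))
    ET.indent(root)
    data = ET.tostring(root, encoding="unicode")
    Path(path).write_text(data + "\n", encoding="utf-8", newline="\n")


def regin_from_xgmml(doc: XgmmlDocument, name: str | None = None) -> tuple[RegIN, list[str]]:
    """Build a RegIN from a parsed document; returns (regin, warnings).

    Duplicate (source, target) interactions are collapsed with their
    evidence concatenated — an extension run adds at most one edge per
    RegIN per pair, so parallel duplicates inside one RegIN would inflate
    support counts.  Validation problems that cannot corrupt the result
    (identifier-less nodes) are warnings, not errors.
    """
    if not doc.directed:
        raise XgmmlFormatError("RegIN must be directed")
    warnings: list[str] = []
    regin = RegIN(
        name=name or doc.label or "unnamed",
        database=str(doc.attributes.get("database", "unknown")),
        version=str(doc.attributes.get("version", "unknown")),
        organism=str(doc.attributes.get("organism", "unknown")),
        interaction_type=str(doc.attributes.get("type", "unknown")),
    )
    for node in doc.nodes:
        raw_ids = node.attributes.get("identifiers", [])
        if isinstance(raw_ids, str):
            raw_ids = [raw_ids] if raw_ids else []
        idset = IdentifierSet.parse(raw_ids)
        if not idset:
            warnings.append(
                f"RegIN {regin.name!r}: node {node.node_id!r} has no identifiers "
                "and cannot match"
            )
        regin.add_node(
            RegINNode(
                node_id=node.node_id,
                label=node.label,
                identifiers=idset,
                biotype=Biotype.coerce(str(node.attributes.get("biotype", "other"))),
                extra={
                    k: str(v)
                    for k, v in node.attributes.items()
                    if k not in ("identifiers", "biotype") and not isinstance(v, list)
                },
            )
        )
    merged: dict[tuple[str, str], RegulatoryInteraction] = {}
    for edge in doc.edges:
        pair = (edge.source, edge.target)
        itype = str(edge.attributes.get("interaction", regin.interaction_type))
        evidence: dict[str, list[str]] = {}
        for k, v in edge.attributes.items():
            if k == "interaction":
                continue
            evidence[k] = [str(m) for m in v] if isinstance(v, list) else [str(v)]
        if pair in merged:
            existing = merged[pair]
            for k, vals in evidence.items():
                bucket = existing.evidence.setdefault(k, [])
                bucket.extend(v for v in vals if v not in bucket)
            warnings.append(
                f"RegIN {regin.name!r}: duplicate interaction "
                f"{pair[0]!r} -> {pair[1]!r} collapsed, evidence merged"
            )
        else:
            merged[pair] = RegulatoryInteraction(
                source_id=edge.source,
                target_id=edge.target,
                interaction_type=itype,
                evidence=evidence,
            )
    regin.interactions = list(merged.values())
    regin.validate_refs()
    return regin, warnings


def load_regin(path: str | Path) -> tuple[RegIN, list[str]]:
    """Read an XGMML file straight into a RegIN (file stem as fallback name)."""
    path = Path(path)
    doc = read_xgmml(path)
    return regin_from_xgmml(doc, name=doc.label or path.stem)


def document_from_regin(regin: RegIN) -> XgmmlDocument:
    """Serialisable form of a RegIN (inverse of :func:`regin_from_xgmml`)."""
    doc = XgmmlDocument(label=regin.name, directed=True)
    doc.attributes.update(
        {
            "database": regin.database,
            "version": regin.version,
            "organism": regin.organism,
            "type": regin.interaction_type,
        }
    )
    for node in regin.nodes.values():
        attrs: dict = {"identifiers": node.identifiers.encode(), "biotype": node.biotype.value}
        attrs.update(node.extra)
        doc.nodes.append(XgmmlNode(node_id=node.node_id, label=node.label, attributes=attrs))
    for it in regin.interactions:
        attrs = {"interaction": it.interaction_type}
        for k, vals in sorted(it.evidence.items()):
            attrs[k] = list(vals)
        doc.edges.append(XgmmlEdge(source=it.source_id, target=it.target_id, attributes=attrs))
    return doc


def save_regin(regin: RegIN, path: str | Path) -> None:
    write_xgmml(document_from_regin(regin), path)


def _open_text(path: Path) -> io.TextIOWrapper:
    # tolerate a UTF-8 BOM and both line-ending conventions
    raw = path.read_bytes()
    if raw.startswith(codecs.BOM_UTF8):
        raw = raw[len(codecs.BOM_UTF8):]
    return io.StringIO(raw.decode("utf-8"))


def seed_from_file(
    path: str | Path,
    format: str,
    id_attribute: str = "id",
) -> tuple[SeedNetwork, list[str]]:
    """Load a seed network from XGMML, SIF or a one-column node list.

    For SIF (``source interaction target`` lines) and node lists the node
    id doubles as the matching attribute value.  Returns (seed, warnings).
    """
    path = Path(path)
    warnings: list[str] = []
    if format == "xgmml":
        doc = read_xgmml(path)
        seed = SeedNetwork(
            id_attribute=id_attribute,
            directed=doc.directed,
            label=doc.label or path.stem,
        )
        for node in doc.nodes:
            attrs = dict(node.attributes)
            attrs.setdefault("label", node.label)
            seed.nodes[node.node_id] = attrs
        for edge in doc.edges:
            seed.edges.append((edge.source, edge.target, dict(edge.attributes)))
        if seed.nodes and not seed.has_id_attribute():
            warnings.append(
                f"id attribute {id_attribute!r} absent from all seed nodes; "
                "extension will add nothing"
            )
    elif format == "sif":
        seed = SeedNetwork(id_attribute=id_attribute, directed=False, label=path.stem)
        for lineno, line in enumerate(_open_text(path), 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) == 1:
                seed.nodes.setdefault(parts[0], {id_attribute: parts[0]})
            elif len(parts) >= 3:
                src, interaction = parts[0], parts[1]
                for tgt in parts[2:]:
                    seed.nodes.setdefault(src, {id_attribute: src})
                    seed.nodes.setdefault(tgt, {id_attribute: tgt})
                    seed.edges.append((src, tgt, {"interaction": interaction}))
            else:
                raise XgmmlFormatError(
                    f"{path}:{lineno}: SIF line needs 'source interaction target'"
                )
    elif format == "nodelist":
        seed = SeedNetwork(id_attribute=id_attribute, directed=False, label=path.stem)
        for line in _open_text(path):
            value = line.strip()
            if value:
                seed.nodes.setdefault(value, {id_attribute: value})
    else:
        raise ValueError(f"unknown seed format {format!r} (xgmml, sif, nodelist)")
    if not seed.nodes:
        warnings.append(f"{path}: empty seed network")
    return seed, warnings


def document_from_extended(extended) -> XgmmlDocument:
    """Flatten an :class:`~reglink.graph_model.ExtendedNetwork` for writing.

    Provenance, origin, visibility and style hints are already plain string
    attributes on the graph elements, so they survive any XGMML writer.
    """
    doc = XgmmlDocument(label=extended.label, directed=True)
    doc.attributes["threshold"] = extended.threshold
    doc.attributes["regins"] = list(extended.regin_names)
    doc.attributes["hidden-regins"] = [
        name for name in extended.regin_names if not extended.visibility.get(name, True)
    ]
    for node_id, attrs in extended.graph.nodes(data=True):
        doc.nodes.append(
            XgmmlNode(
                node_id=str(node_id),
                label=str(attrs.get("label", node_id)),
                attributes={k: v for k, v in attrs.items() if k != "label"},
            )
        )
    for u, v, _key, attrs in extended.graph.edges(keys=True, data=True):
        doc.edges.append(XgmmlEdge(source=str(u), target=str(v), attributes=dict(attrs)))
    return doc
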