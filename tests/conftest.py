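"""Shared helpers: independent brute-force oracles and random instances.

The oracle here re-derives the extension contract with plain double/triple
loops and inline canonical-key logic — it never calls the linker or the
canonical_key implementation, so agreement with the package is a genuine
cross-check.
"""

from __future__ import annotations

import random
from collections import Counter

import pytest

from reglink.graph_model import Biotype, IdentifierSet, SeedNetwork
from reglink.graph_model import RegIN, RegINNode, RegulatoryInteraction


# ---------------------------------------------------------------------------
# brute-force extension oracle

def oracle_canonical(identifiers: IdentifierSet, priority) -> str:
    """Priority-pick re-derived independently of graph_model.canonical_key."""
    pairs = sorted(identifiers.entries)
    for system in priority:
        candidates = sorted(v for s, v in pairs if s == system)
        if candidates:
            return candidates[0]
    return sorted(v for _, v in pairs)[0]


def oracle_extend(seed: SeedNetwork, regins, direction, priority) -> Counter:
    """Multiset of (source graph id, target graph id, regin name) triples.

    Triple loop: for every RegIN, every interaction, every seed node;
    graph ids follow the documented convention (seed node id for matching
    endpoints, ``added::<canonical>`` otherwise, with a per-RegIN key for
    identifier-less nodes).
    """
    edges: Counter = Counter()
    for regin in regins:
        attach: dict[str, list[str]] = {}
        for regin_node in regin.nodes.values():
            for seed_id in seed.nodes:
                if set(seed.id_values(seed_id)) & set(regin_node.identifiers.values()):
                    attach.setdefault(regin_node.node_id, []).append(seed_id)
        for it in regin.interactions:
            src_seed = attach.get(it.source_id, [])
            tgt_seed = attach.get(it.target_id, [])
            if direction == "targets":
                qualifies = bool(src_seed)
            elif direction == "regulators":
                qualifies = bool(tgt_seed)
            else:
                qualifies = bool(src_seed) or bool(tgt_seed)
            if not qualifies:
                continue

            def added_id(node_id):
                node = regin.nodes[node_id]
                if not node.identifiers:
                    return f"added::{regin.name}::{node_id}"
                return "added::" + oracle_canonical(node.identifiers, priority)

            sources = src_seed or [added_id(it.source_id)]
            targets = tgt_seed or [added_id(it.target_id)]
            for u in sources:
                for v in targets:
                    edges[(u, v, regin.name)] += 1
    return edges


def extracted_edges(extended) -> Counter:
    """The same triple multiset, read off an ExtendedNetwork."""
    from reglink.graph_model import REGIN_ATTR

    return Counter((u, v, d[REGIN_ATTR]) for u, v, _k, d in extended.added_edges())


# ---------------------------------------------------------------------------
# random instances (messier than the constructive generator: shared
# identifier values, identifier-less nodes, self-loops, multi-system ids)

SYSTEMS = ("ensembl", "ncbigene", "uniprot", "unknown")
PRIORITY = ("ensembl", "ncbigene", "uniprot")


def random_instance(rng: random.Random, max_seed=50, max_regins=5, max_interactions=300):
    n_seed = rng.randint(0, max_seed)
    n_regins = rng.randint(1, max_regins)
    # shared pool: collisions (ambiguous matches) happen but stay sparse
    pool_size = rng.randint(30, 120)
    values = [f"V{i:03d}" for i in range(pool_size)]

    seed = SeedNetwork(id_attribute="xref", directed=False, label="rand-seed")
    for i in range(n_seed):
        attrs = {}
        if rng.random() < 0.9:  # some nodes lack the matching attribute
            k = rng.randint(1, 3)
            vals = rng.sample(values, min(k, len(values)))
            attrs["xref"] = vals if len(vals) > 1 or rng.random() < 0.5 else vals[0]
        seed.nodes[f"n{i}"] = attrs
    for _ in range(rng.randint(0, n_seed)):
        if n_seed >= 2:
            u, v = rng.sample(list(seed.nodes), 2)
            seed.edges.append((u, v, {"interaction": "pp"}))

    regins = []
    for r in range(n_regins):
        regin = RegIN(
            name=f"R{r}", database=f"db{r}", version="1", organism="test",
            interaction_type="reg",
        )
        n_nodes = rng.randint(2, max(2, max_interactions // 3))
        for j in range(n_nodes):
            if rng.random() < 0.05:
                idset = IdentifierSet()  # identifier-less: can never match
            else:
                entries = []
                for _ in range(rng.randint(1, 3)):
                    entries.append((rng.choice(SYSTEMS), rng.choice(values)))
                idset = IdentifierSet(entries)
            regin.add_node(
                RegINNode(
                    node_id=f"R{r}x{j}", label=f"R{r}x{j}", identifiers=idset,
                    biotype=Biotype.other,
                )
            )
        node_ids = list(regin.nodes)
        pairs = set()
        for _ in range(rng.randint(0, max_interactions)):
            u = rng.choice(node_ids)
            v = rng.choice(node_ids)  # self-loops possible
            if (u, v) in pairs:
                continue
            pairs.add((u, v))
            regin.interactions.append(
                RegulatoryInteraction(
                    source_id=u, target_id=v, interaction_type="reg",
                    evidence={"pmid": [str(rng.randrange(10**6))]},
                )
            )
        regins.append(regin)
    return seed, regins


# ---------------------------------------------------------------------------
# random XGMML documents for round-trip tests

def random_document(rng: random.Random):
    from reglink.xgmml_io import XgmmlDocument, XgmmlEdge, XgmmlNode

    doc = XgmmlDocument(
        label=f"doc{rng.randrange(1000)}",
        directed=rng.random() < 0.5,
    )
    for k in range(rng.randint(0, 3)):
        doc.attributes[f"g{k}"] = rng.choice(
            ["text", rng.randint(-5, 5), rng.random(), ["a", "b", f"m{k}"]]
        )
    n_nodes = rng.randint(0, 12)
    for i in range(n_nodes):
        attrs = {}
        for k in range(rng.randint(0, 4)):
            attrs[f"a{k}"] = rng.choice(
                [
                    f"s{rng.randrange(100)}",
                    rng.randint(-100, 100),
                    round(rng.uniform(-10, 10), 6),
                    [f"x{j}" for j in range(rng.randint(0, 4))],
                ]
            )
        doc.nodes.append(XgmmlNode(node_id=f"n{i}", label=f"L{i}", attributes=attrs))
    if n_nodes:
        for _ in range(rng.randint(0, 20)):  # parallel edges likely
            doc.edges.append(
                XgmmlEdge(
                    source=f"n{rng.randrange(n_nodes)}",
                    target=f"n{rng.randrange(n_nodes)}",
                    attributes={"tag": f"t{rng.randrange(3)}", "members": ["p", "q"]},
                )
            )
    return doc


def doc_signature(doc):
    """Order-insensitive-within-attributes equality key for documents."""

    def norm(value):
        if isinstance(value, list):
            return ("list", tuple(str(v) for v in value))
        return (type(value).__name__, value)

    return (
        doc.label,
        doc.directed,
        tuple(sorted((k, norm(v)) for k, v in doc.attributes.items())),
        tuple(
            (n.node_id, n.label, tuple(sorted((k, norm(v)) for k, v in n.attributes.items())))
            for n in doc.nodes
        ),
        tuple(
            (e.source, e.target, tuple(sorted((k, norm(v)) for k, v in e.attributes.items())))
            for e in doc.edges
        ),
    )


@pytest.fixture
def toy():
    from reglink.synthetic_fixtures import figure1_toy

    return figure1_toy()
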