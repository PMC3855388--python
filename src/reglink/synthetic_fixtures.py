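"""Deterministic generator of seed networks and RegIN collections.

Stands in for downloaded interaction-database RegINs so the whole pipeline
can be exercised without network access or licensed data.  The generator
controls cross-RegIN overlap exactly and records, for every generated
interaction, the supporting RegIN set and which direction modes it
qualifies under — bookkeeping done constructively at generation time,
never by running the linker, so agreement between the two is a genuine
oracle test.

Identifiers are drawn from two fake secondary systems ("sysA", "sysB")
plus a fake primary ("sysP"), exercising multi-system matching and
canonical-key merging.  The distributions are not statistically realistic
miRNA/TF/drug interactomes; they only exercise the code paths.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .graph_model import (
    Biotype,
    DEFAULT_CANONICAL_PRIORITY,
    IdentifierSet,
    RegIN,
    RegINNode,
    RegulatoryInteraction,
    SeedNetwork,
)
from .xgmml_io import save_regin, write_xgmml, XgmmlDocument, XgmmlNode, XgmmlEdge

FIXTURE_PRIORITY = ("sysP", "sysA", "sysB")


@dataclass
class FixtureSpec:
    """Shape parameters of one synthetic instance."""

    n_seed_nodes: int = 10
    n_regins: int = 3
    regulators_per_regin: int = 8
    interactions_per_regin: int = 40
    overlap_fraction: float = 0.2
    #: fraction of seed-touching interactions where the seed molecule is
    #: the target (regulator -> seed); the rest have the seed as regulator
    direction_mix: float = 0.5
    #: fraction of interactions touching no seed molecule at all, so the
    #: extension has true negatives to leave out
    distractor_fraction: float = 0.2
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_seed_nodes", "n_regins", "regulators_per_regin",
                     "interactions_per_regin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("overlap_fraction", "direction_mix", "distractor_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.overlap_fraction > 0 and self.n_regins < 2:
            raise ValueError("overlap_fraction > 0 needs at least 2 RegINs")


@dataclass
class GroundTruth:
    """Construction-time record of what extension must produce.

    ``expected_edges[mode]`` is the set of (graph source id, graph target
    id, regin name) triples the linker must add under that direction mode;
    graph ids are seed node ids for seed molecules and ``"added::<key>"``
    for off-seed molecules.  ``node_canonical`` maps every graph id that
    can appear to its canonical endpoint key.
    """

    expected_edges: dict[str, set[tuple[str, str, str]]] = field(
        default_factory=lambda: {"targets": set(), "regulators": set(), "both": set()}
    )
    node_canonical: dict[str, str] = field(default_factory=dict)

    def expected_support(self, mode: str = "both") -> dict[tuple[str, str], set[str]]:
        support: dict[tuple[str, str], set[str]] = {}
        for u, v, regin in self.expected_edges[mode]:
            pair = (self.node_canonical[u], self.node_canonical[v])
            support.setdefault(pair, set()).add(regin)
        return support

    def expected_added_nodes(self, mode: str = "both") -> set[str]:
        nodes = set()
        for u, v, _ in self.expected_edges[mode]:
            for endpoint in (u, v):
                if endpoint.startswith("added::"):
                    nodes.add(endpoint)
        return nodes

    def to_dict(self) -> dict:
        return {
            "expected_edges": {
                mode: sorted(list(t) for t in triples)
                for mode, triples in self.expected_edges.items()
            },
            "node_canonical": dict(sorted(self.node_canonical.items())),
        }


class _Molecule:
    __slots__ = ("primary", "identifiers", "label", "biotype", "is_seed", "seed_node_id")

    def __init__(self, primary, identifiers, label, biotype, is_seed, seed_node_id=None):
        self.primary = primary
        self.identifiers = identifiers
        self.label = label
        self.biotype = biotype
        self.is_seed = is_seed
        self.seed_node_id = seed_node_id


def generate(spec: FixtureSpec) -> tuple[SeedNetwork, list[RegIN], GroundTruth]:
    """Generate (seed, RegINs, ground truth); same rng_seed, same output."""
    spec.validate()
    rng = random.Random(spec.rng_seed)
    truth = GroundTruth()

    # --- molecule universe -------------------------------------------------
    seed_molecules: list[_Molecule] = []
    seed = SeedNetwork(id_attribute="ids", directed=False, label="synthetic-seed")
    for i in range(spec.n_seed_nodes):
        primary = f"P-seed{i:03d}"
        idents = [("sysP", primary), ("sysA", f"A-seed{i:03d}")]
        if rng.random() < 0.5:
            idents.append(("sysB", f"B-seed{i:03d}"))
        mol = _Molecule(primary, idents, f"seed{i}", Biotype.gene, True, f"s{i:03d}")
        seed_molecules.append(mol)
        # the seed node carries a subset of the molecule's identifiers in
        # its matching attribute, so matching crosses identifier systems
        carried = [primary]
        if rng.random() < 0.6:
            carried.append(f"A-seed{i:03d}")
        seed.nodes[mol.seed_node_id] = {"ids": carried, "label": mol.label}
        truth.node_canonical[mol.seed_node_id] = min(carried)
    # a few seed-seed edges so conservation is non-trivial
    seed_ids = list(seed.nodes)
    for _ in range(min(len(seed_ids), 5)):
        if len(seed_ids) >= 2:
            u, v = rng.sample(seed_ids, 2)
            seed.edges.append((u, v, {"interaction": "pp"}))

    n_regulators = spec.n_regins * spec.regulators_per_regin
    regulators: list[_Molecule] = []
    for j in range(n_regulators):
        primary = f"P-reg{j:03d}"
        idents = [("sysP", primary), ("sysA", f"A-reg{j:03d}"), ("sysB", f"B-reg{j:03d}")]
        regulators.append(_Molecule(primary, idents, f"reg{j}", Biotype.microRNA, False))
    n_extras = max(spec.interactions_per_regin, 4)
    extras: list[_Molecule] = []
    for j in range(n_extras):
        primary = f"P-ext{j:03d}"
        idents = [("sysP", primary), ("sysA", f"A-ext{j:03d}")]
        extras.append(_Molecule(primary, idents, f"ext{j}", Biotype.gene, False))
    for mol in regulators + extras:
        truth.node_canonical[f"added::{mol.primary}"] = mol.primary

    def graph_id(mol: _Molecule) -> str:
        return mol.seed_node_id if mol.is_seed else f"added::{mol.primary}"

    # --- interaction plan --------------------------------------------------
    def draw_interaction():
        """(regulator molecule, target molecule, touches) by construction."""
        if seed_molecules and rng.random() >= spec.distractor_fraction:
            seed_mol = rng.choice(seed_molecules)
            if rng.random() < spec.direction_mix:
                reg = rng.choice(regulators) if regulators else rng.choice(seed_molecules)
                return reg, seed_mol
            tgt = rng.choice(extras + seed_molecules) if rng.random() < 0.15 else rng.choice(extras)
            return seed_mol, tgt
        reg = rng.choice(regulators) if regulators else None
        tgt = rng.choice(extras) if extras else None
        if reg is None or tgt is None:
            return None, None
        return reg, tgt

    regin_pairs: list[dict[tuple[str, str], tuple[_Molecule, _Molecule]]] = [
        {} for _ in range(spec.n_regins)
    ]
    shared_quota = [
        round(spec.overlap_fraction * spec.interactions_per_regin)
        for _ in range(spec.n_regins)
    ]
    # shared interactions: each duplicated into exactly two RegINs
    guard = 0
    while sum(1 for q in shared_quota if q > 0) >= 2 and guard < 10000:
        guard += 1
        candidates = [i for i, q in enumerate(shared_quota) if q > 0]
        a, b = rng.sample(candidates, 2)
        reg, tgt = draw_interaction()
        if reg is None:
            break
        pair = (reg.primary, tgt.primary)
        if pair in regin_pairs[a] or pair in regin_pairs[b]:
            continue
        regin_pairs[a][pair] = (reg, tgt)
        regin_pairs[b][pair] = (reg, tgt)
        shared_quota[a] -= 1
        shared_quota[b] -= 1
    # unique fill to quota
    for i in range(spec.n_regins):
        guard = 0
        while len(regin_pairs[i]) < spec.interactions_per_regin and guard < 10000:
            guard += 1
            reg, tgt = draw_interaction()
            if reg is None:
                break
            pair = (reg.primary, tgt.primary)
            if any(pair in pairs for pairs in regin_pairs):
                continue  # keep unique fills unique across RegINs
            regin_pairs[i][pair] = (reg, tgt)

    # --- materialise RegINs + ground truth ---------------------------------
    regins: list[RegIN] = []
    for i in range(spec.n_regins):
        regin = RegIN(
            name=f"regin-{i:02d}",
            database=f"syntheticdb-{i}",
            version="1.0",
            organism="synthetic",
            interaction_type="synthetic regulation",
        )
        for pair in sorted(regin_pairs[i]):
            reg, tgt = regin_pairs[i][pair]
            for mol in (reg, tgt):
                if mol.primary not in regin.nodes:
                    regin.add_node(
                        RegINNode(
                            node_id=mol.primary,
                            label=mol.label,
                            identifiers=IdentifierSet(mol.identifiers),
                            biotype=mol.biotype,
                        )
                    )
            regin.interactions.append(
                RegulatoryInteraction(
                    source_id=reg.primary,
                    target_id=tgt.primary,
                    interaction_type=regin.interaction_type,
                    evidence={"pmid": [f"90{rng.randrange(10000):05d}"]},
                )
            )
            q_targets = reg.is_seed
            q_regulators = tgt.is_seed
            triple = (graph_id(reg), graph_id(tgt), regin.name)
            if q_targets:
                truth.expected_edges["targets"].add(triple)
            if q_regulators:
                truth.expected_edges["regulators"].add(triple)
            if q_targets or q_regulators:
                truth.expected_edges["both"].add(triple)
        regins.append(regin)
    return seed, regins, truth


def write_fixture(
    seed: SeedNetwork,
    regins: list[RegIN],
    truth: GroundTruth,
    outdir: str | Path,
) -> None:
    """Write seed + RegINs (XGMML) and ground truth (JSON) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    doc = XgmmlDocument(label=seed.label, directed=seed.directed)
    for node_id, attrs in seed.nodes.items():
        a = dict(attrs)
        label = str(a.pop("label", node_id))
        doc.nodes.append(XgmmlNode(node_id=node_id, label=label, attributes=a))
    for u, v, attrs in seed.edges:
        doc.edges.append(XgmmlEdge(source=u, target=v, attributes=dict(attrs)))
    write_xgmml(doc, outdir / "seed.xgmml")
    for regin in regins:
        save_regin(regin, outdir / f"{regin.name}.xgmml")
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def figure1_toy() -> tuple[SeedNetwork, list[RegIN], GroundTruth]:
    """Fixed four-RegIN miRNA-target workflow fixture.

    Four seed miRNAs; two large "predicted" RegINs and two small
    "validated" ones with designed per-RegIN added-interaction counts
    (40, 28, 6, 3) under ``direction="targets"``; exactly five
    miRNA-target pairs are supported by two or more RegINs, and hiding
    both predicted RegINs leaves the 9 validated edges.  All identifiers
    are synthetic lookalikes, not real database records.
    """
    truth = GroundTruth()
    seed = SeedNetwork(id_attribute="identifier", directed=False, label="mirna-seed")
    mirnas = {}
    for i in range(1, 5):
        accession = f"MIMAT{9000000 + i}"
        node_id = f"mir{i}"
        seed.nodes[node_id] = {
            "identifier": accession,
            "label": f"syn-miR-{i}",
        }
        mirnas[i] = (node_id, accession)
        truth.node_canonical[node_id] = accession

    gene_ids: dict[str, str] = {}

    def gene(tag: str) -> str:
        if tag not in gene_ids:
            gene_ids[tag] = f"ENSG{90000000 + len(gene_ids):011d}"
        return gene_ids[tag]

    # five designed overlap pairs: (miRNA index, gene tag, supporting RegINs)
    overlap_plan = [
        (1, "G001", ("predicted-A", "validated-C")),
        (1, "G002", ("predicted-A", "predicted-B")),
        (2, "G003", ("predicted-A", "predicted-B", "validated-C", "validated-D")),
        (3, "G004", ("validated-C", "validated-D")),
        (4, "G005", ("predicted-A", "predicted-B")),
    ]
    specs = {
        "predicted-A": ("syntheticscan", "predicted MTI", 40),
        "predicted-B": ("syntheticcosm", "predicted MTI", 28),
        "validated-C": ("synthetictarbase", "validated MTI", 6),
        "validated-D": ("syntheticrecords", "validated MTI", 3),
    }
    plan: dict[str, list[tuple[int, str]]] = {name: [] for name in specs}
    for mir, tag, supporters in overlap_plan:
        for name in supporters:
            plan[name].append((mir, tag))
    unique_counter = 0
    for name, (_db, _type, total) in specs.items():
        mir_cycle = 0
        while len(plan[name]) < total:
            unique_counter += 1
            mir_cycle = mir_cycle % 4 + 1
            plan[name].append((mir_cycle, f"U{unique_counter:03d}"))

    regins = []
    for name, (db, itype, total) in specs.items():
        regin = RegIN(
            name=name,
            database=db,
            version="r1",
            organism="synthetic-human",
            interaction_type=itype,
        )
        for mir, tag in plan[name]:
            node_id, accession = mirnas[mir]
            ensg = gene(tag)
            if accession not in regin.nodes:
                regin.add_node(
                    RegINNode(
                        node_id=accession,
                        label=f"syn-miR-{mir}",
                        identifiers=IdentifierSet(
                            [("miRBase-accession", accession),
                             ("miRBase-id", f"syn-miR-{mir}")]
                        ),
                        biotype=Biotype.microRNA,
                    )
                )
            if ensg not in regin.nodes:
                regin.add_node(
                    RegINNode(
                        node_id=ensg,
                        label=tag,
                        identifiers=IdentifierSet(
                            [("ensembl", ensg), ("ncbigene", str(60000 + int(ensg[-5:])))]
                        ),
                        biotype=Biotype.gene,
                    )
                )
            regin.interactions.append(
                RegulatoryInteraction(
                    source_id=accession,
                    target_id=ensg,
                    interaction_type=itype,
                    evidence={"pmid": [f"88{len(regin.interactions):06d}"]},
                )
            )
            added_gene = f"added::{ensg}"
            truth.node_canonical[added_gene] = ensg
            triple = (node_id, added_gene, name)
            truth.expected_edges["targets"].add(triple)
            truth.expected_edges["both"].add(triple)
        assert len(regin.interactions) == total
        regins.append(regin)
    return seed, regins, truth
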