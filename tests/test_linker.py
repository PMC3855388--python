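"""Extension algorithm: spec'd behaviour, oracle equivalence, invariants."""

import random
from collections import Counter

import pytest

from reglink.graph_model import (
    Biotype,
    IdentifierSet,
    ORIGIN_ATTR,
    REGIN_ATTR,
    RegIN,
    RegINNode,
    RegulatoryInteraction,
    SeedNetwork,
)
from reglink.linker import LinkConfig, extend, index_regin, link_stats, match_seed, recover_seed

from conftest import PRIORITY, extracted_edges, oracle_extend, random_instance


def mk_regin(name, nodes, interactions, **meta):
    regin = RegIN(name=name, **meta)
    for node_id, idents in nodes.items():
        regin.add_node(
            RegINNode(
                node_id=node_id,
                label=node_id,
                identifiers=IdentifierSet(idents),
                biotype=Biotype.other,
            )
        )
    for src, tgt in interactions:
        regin.interactions.append(
            RegulatoryInteraction(source_id=src, target_id=tgt, interaction_type="reg")
        )
    return regin


def mk_seed(values_by_node, id_attribute="xref"):
    seed = SeedNetwork(id_attribute=id_attribute)
    for node, values in values_by_node.items():
        seed.nodes[node] = {id_attribute: values}
    return seed


MTI_REGIN = {
    "M1": [("miRBase-accession", "MIMAT1")],
    "M2": [("miRBase-accession", "MIMAT2")],
    "G1": [("ensembl", "E1")],
    "G2": [("ensembl", "E2")],
    "G3": [("ensembl", "E3")],
}
MTI_EDGES = [("M1", "G1"), ("M1", "G2"), ("M2", "G3")]


def test_index_regin_maps_every_value():
    regin = mk_regin("A", {"N": [("ensembl", "E1"), ("ncbigene", "1")]}, [])
    index, notes = index_regin(regin)
    assert index == {"E1": {"N"}, "1": {"N"}}
    assert notes == []


def test_index_regin_notes_shared_values():
    regin = mk_regin("A", {"N1": [("ensembl", "X")], "N2": [("ncbigene", "X")]}, [])
    index, notes = index_regin(regin)
    assert index["X"] == {"N1", "N2"}
    assert len(notes) == 1


def test_index_equals_linear_scan_on_random_regins():
    rng = random.Random(5)
    for _ in range(20):
        _, regins = random_instance(rng, max_seed=0, max_regins=1, max_interactions=50)
        regin = regins[0]
        index, _ = index_regin(regin)
        expected = {}
        for node in regin.nodes.values():
            for value in node.identifiers.values():
                expected.setdefault(value, set()).add(node.node_id)
        assert index == expected


def test_match_is_exact_and_case_sensitive():
    regin = mk_regin("A", {"N": [("ensembl", "E1")]}, [])
    assert match_seed(mk_seed({"s": "E1"}), regin) == {"s": {"N"}}
    assert match_seed(mk_seed({"s": "e1"}), regin) == {}
    assert match_seed(mk_seed({"s": []}), regin) == {}


def test_match_equals_double_loop_on_random_instances():
    rng = random.Random(11)
    for _ in range(20):
        seed, regins = random_instance(rng, max_seed=20, max_regins=1, max_interactions=60)
        regin = regins[0]
        expected = {}
        for sid in seed.nodes:
            for node in regin.nodes.values():
                if set(seed.id_values(sid)) & set(node.identifiers.values()):
                    expected.setdefault(sid, set()).add(node.node_id)
        assert match_seed(seed, regin) == expected


def test_add_regulators_targets_the_seed_genes():
    """'Add regulators' looks for interactions that target the seed nodes."""
    seed = mk_seed({"g1": "E1"})
    regin = mk_regin("A", MTI_REGIN, MTI_EDGES)
    ext, report = extend(seed, LinkConfig(regins=[regin], direction="regulators"))
    triples = extracted_edges(ext)
    assert triples == Counter({("added::MIMAT1", "g1", "A"): 1})
    assert ext.added_nodes() == ["added::MIMAT1"]
    assert report.per_regin["A"]["added_interactions"] == 1


def test_add_targets_adds_downstream_genes():
    seed = mk_seed({"m1": "MIMAT1"})
    regin = mk_regin("A", MTI_REGIN, MTI_EDGES)
    ext, _ = extend(seed, LinkConfig(regins=[regin], direction="targets"))
    triples = extracted_edges(ext)
    assert triples == Counter(
        {("m1", "added::E1", "A"): 1, ("m1", "added::E2", "A"): 1}
    )


def test_shared_interaction_gives_parallel_edges_one_merged_node():
    seed = mk_seed({"g1": "E1"})
    a = mk_regin("A", MTI_REGIN, [("M1", "G1")])
    b = mk_regin("B", MTI_REGIN, [("M1", "G1")])
    ext, _ = extend(seed, LinkConfig(regins=[a, b], direction="regulators"))
    assert ext.added_nodes() == ["added::MIMAT1"]  # same miRNA from both: one node
    triples = extracted_edges(ext)
    assert triples == Counter(
        {("added::MIMAT1", "g1", "A"): 1, ("added::MIMAT1", "g1", "B"): 1}
    )


def test_no_regins_is_identity():
    seed = mk_seed({"a": "x"})
    seed.edges.append(("a", "a", {"interaction": "self"}))
    ext, report = extend(seed, LinkConfig(regins=[]))
    assert ext.added_edges() == [] and ext.added_nodes() == []
    assert report.per_regin == {}
    assert recover_seed(ext).nodes == seed.nodes


def test_interaction_between_two_seed_nodes_adds_edge_no_nodes():
    seed = mk_seed({"tf": "E1", "g": "E3"})
    regin = mk_regin("A", MTI_REGIN, [("G1", "G3")])
    ext, report = extend(seed, LinkConfig(regins=[regin], direction="both"))
    assert extracted_edges(ext) == Counter({("tf", "g", "A"): 1})
    assert ext.added_nodes() == []
    assert report.per_regin["A"]["added_nodes"] == 0


def test_missing_id_attribute_everywhere_warns_and_adds_nothing():
    seed = SeedNetwork(id_attribute="entrez")
    seed.nodes["a"] = {"symbol": "TP53"}
    regin = mk_regin("A", MTI_REGIN, MTI_EDGES)
    ext, report = extend(seed, LinkConfig(regins=[regin]))
    assert ext.added_edges() == []
    assert any("absent from all seed nodes" in d for d in report.diagnostics)


def test_ambiguous_seed_match_takes_union_with_diagnostic():
    regin = mk_regin(
        "A",
        {"N1": [("ensembl", "X")], "N2": [("ncbigene", "X")], "T": [("ensembl", "E9")]},
        [("N1", "T"), ("N2", "T")],
    )
    seed = mk_seed({"s": "X"})
    ext, report = extend(seed, LinkConfig(regins=[regin], direction="targets"))
    assert extracted_edges(ext) == Counter({("s", "added::E9", "A"): 2})
    assert any("matches 2 RegIN nodes" in d for d in report.diagnostics)


def test_self_loop_added_and_flagged():
    regin = mk_regin("A", {"G1": [("ensembl", "E1")]}, [("G1", "G1")])
    seed = mk_seed({"g": "E1"})
    ext, report = extend(seed, LinkConfig(regins=[regin]))
    assert extracted_edges(ext) == Counter({("g", "g", "A"): 1})
    assert any("self-loop" in d for d in report.diagnostics)


def test_duplicate_regin_names_rejected():
    with pytest.raises(ValueError, match="pairwise distinct"):
        extend(mk_seed({}), LinkConfig(regins=[mk_regin("A", {}, []), mk_regin("A", {}, [])]))


def test_extending_an_extended_network_is_refused():
    seed = mk_seed({"g1": "E1"})
    regin = mk_regin("A", MTI_REGIN, MTI_EDGES)
    ext, _ = extend(seed, LinkConfig(regins=[regin]))
    recovered = SeedNetwork(id_attribute="xref")
    for node, attrs in ext.graph.nodes(data=True):
        recovered.nodes[node] = dict(attrs)
    with pytest.raises(ValueError, match="already carries extension provenance"):
        extend(recovered, LinkConfig(regins=[regin]))


# --- randomized invariants -------------------------------------------------

def test_extend_matches_brute_force_oracle_all_directions():
    rng = random.Random(77)
    for _ in range(40):
        seed, regins = random_instance(rng, max_seed=25, max_regins=4, max_interactions=80)
        for direction in ("targets", "regulators", "both"):
            ext, _ = extend(
                seed,
                LinkConfig(regins=regins, direction=direction, canonical_priority=PRIORITY),
            )
            assert extracted_edges(ext) == oracle_extend(seed, regins, direction, PRIORITY)


def test_direction_both_is_union_of_targets_and_regulators():
    rng = random.Random(13)
    for _ in range(25):
        seed, regins = random_instance(rng, max_seed=25, max_regins=4, max_interactions=80)
        sets = {}
        for direction in ("targets", "regulators", "both"):
            ext, _ = extend(
                seed,
                LinkConfig(regins=regins, direction=direction, canonical_priority=PRIORITY),
            )
            sets[direction] = set(extracted_edges(ext))
        assert sets["both"] == sets["targets"] | sets["regulators"]


def test_seed_subgraph_conserved_exactly():
    rng = random.Random(31)
    for _ in range(20):
        seed, regins = random_instance(rng, max_seed=25, max_regins=3, max_interactions=60)
        ext, _ = extend(seed, LinkConfig(regins=regins, canonical_priority=PRIORITY))
        recovered = recover_seed(ext)
        assert recovered.nodes == seed.nodes
        assert sorted(map(repr, recovered.edges)) == sorted(map(repr, seed.edges))


def test_report_counts_consistent_with_graph():
    rng = random.Random(53)
    for _ in range(20):
        seed, regins = random_instance(rng, max_seed=25, max_regins=4, max_interactions=60)
        ext, report = extend(seed, LinkConfig(regins=regins, canonical_priority=PRIORITY))
        assert report.total_added_interactions() == len(ext.added_edges())
        assert report.total_added_nodes() == len(ext.added_nodes())
        recounted = link_stats(ext)
        for name in report.per_regin:
            assert (
                report.per_regin[name]["added_interactions"]
                == recounted.per_regin[name]["added_interactions"]
            )
            assert (
                report.per_regin[name]["added_nodes"]
                == recounted.per_regin[name]["added_nodes"]
            )
        # every added node has an incident added edge
        touched = set()
        for u, v, _k, _d in ext.added_edges():
            touched.update((u, v))
        assert set(ext.added_nodes()) <= touched


def test_extend_is_deterministic_including_ordering():
    rng1, rng2 = random.Random(97), random.Random(97)
    seed1, regins1 = random_instance(rng1, max_seed=20, max_regins=3, max_interactions=50)
    seed2, regins2 = random_instance(rng2, max_seed=20, max_regins=3, max_interactions=50)
    ext1, rep1 = extend(seed1, LinkConfig(regins=regins1, canonical_priority=PRIORITY))
    ext2, rep2 = extend(seed2, LinkConfig(regins=regins2, canonical_priority=PRIORITY))
    assert list(ext1.graph.nodes(data=True)) == list(ext2.graph.nodes(data=True))
    assert list(ext1.graph.edges(keys=True, data=True)) == list(
        ext2.graph.edges(keys=True, data=True)
    )
    assert rep1.per_regin == rep2.per_regin


def test_any_shared_id_merge_unifies_overlapping_identifier_sets():
    """Two RegINs list one molecule under different primaries but a shared
    secondary id: canonical merging keeps two nodes, any-shared-id one."""
    a = mk_regin("A", {"M": [("ensembl", "EA"), ("ncbigene", "7")],
                       "T": [("ensembl", "E1")]}, [("M", "T")])
    b = mk_regin("B", {"M": [("ensembl", "EB"), ("ncbigene", "7")],
                       "T": [("ensembl", "E1")]}, [("M", "T")])
    seed = mk_seed({"g": "E1"})
    ext_canon, _ = extend(seed, LinkConfig(regins=[a, b], direction="regulators"))
    assert len(ext_canon.added_nodes()) == 2
    ext_merge, _ = extend(
        seed, LinkConfig(regins=[a, b], direction="regulators", merge="any-shared-id")
    )
    assert len(ext_merge.added_nodes()) == 1
    node = ext_merge.added_nodes()[0]
    idents = set(ext_merge.graph.nodes[node]["identifiers"])
    assert {"ensembl:EA", "ensembl:EB", "ncbigene:7"} <= idents
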