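# reglink

Extend biological networks with regulatory interactions — miRNA→target,
transcription-factor→target and drug→target — drawn from *regulatory
interaction network* (RegIN) files, keeping per-source provenance on every
added edge and filtering the result by source visibility and cross-source
overlap.

## The problem

Pathway diagrams, protein–protein networks and gene lists usually contain
little information about *who regulates* their members. That information
lives in many separate interaction databases (predicted and validated
miRNA-target collections, ENCODE-style TF-binding sets, drug-target
registries), each with its own identifier conventions. `reglink` is for
biologists and bioinformaticians who want to graft that regulatory layer
onto a network of interest and then reason about which interactions are
corroborated by more than one source.

## The method

A **RegIN** is a directed network of regulator → target interactions from
one database release, stored as XGMML; each node carries identifiers in
one or more identifier systems (Ensembl gene, NCBI gene, UniProt, miRBase
accession/id, DrugBank). Given a **seed network** whose nodes carry an
identifier attribute, the extension pass:

1. matches seed nodes against RegIN nodes by exact, case-sensitive
   identifier equality (any seed value vs any RegIN node identifier);
2. extracts every interaction *s → t* in which a seed node participates —
   as the regulator (`--direction targets`), as the target
   (`--direction regulators`, i.e. look for interactions that target the
   seed nodes), or either (`both`, the default);
3. grafts each qualifying interaction as **one edge per supporting
   RegIN**, so an interaction present in *k* sources appears as *k*
   parallel edges, each tagged with a single RegIN name; non-matching
   endpoints become added nodes, merged across RegINs by a canonical
   identifier key so the same molecule is a single node.

Extension is one-hop: added nodes are never re-queried. The **support** of
a regulator→target pair is the number of distinct RegINs containing it;
the overlap threshold *k* shows only pairs with support ≥ *k*, and
per-RegIN hide/show removes whole sources — both non-destructively, as
visibility flags that can be restored.

When the seed's identifier system is not embedded in the RegINs, a
cross-reference TSV (one identifier system per column, the layout a
BridgeDb mapping database exports to) translates seed identifiers first;
many-to-many mappings are kept as sets, never silently resolved.

## Worked example

The package ships a deterministic toy fixture shaped like a typical
miRNA workflow: four seed miRNAs, two large "predicted" RegINs and two
small "validated" ones.

```sh
reglink simulate --toy --out toy/
reglink extend --seed toy/seed.xgmml --id-attribute identifier \
    --regins toy/ --direction targets -o extended.xgmml --report report.json
```

prints (to standard error):

```
predicted-A: 40 interactions, 40 nodes added (4 seed nodes matched)
predicted-B: 28 interactions, 25 nodes added (4 seed nodes matched)
validated-C: 6 interactions, 4 nodes added (3 seed nodes matched)
validated-D: 3 interactions, 1 nodes added (3 seed nodes matched)
```

40/28/6/3 are the interactions each RegIN contributed; later RegINs add
fewer nodes than interactions because target genes already introduced by
an earlier RegIN merge into the existing node.
Filtering then isolates corroborated or validated interactions:

```sh
# validated sources only: the 9 red/purple-style edges remain
reglink filter --network extended.xgmml \
    --hide predicted-A --hide predicted-B -o validated.xgmml
# 9 added edges visible at threshold 1

# pairs supported by >= 2 RegINs: exactly 5 survive
reglink filter --network extended.xgmml --threshold 2 -o overlap.xgmml
# 12 added edges visible at threshold 2
```

(12 edges at threshold 2 because the 5 surviving pairs keep all their
parallel provenance edges: 2+2+4+2+2.)

Custom RegINs are built from any tabular interaction dump with
`reglink build-regin --table interactions.tsv --schema schema.yaml -o my.xgmml`,
where the YAML schema names the identifier/label/evidence columns; no
licence-restricted database content ships with this repository.

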