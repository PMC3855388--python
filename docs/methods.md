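# Methods

## The extension model

`reglink` treats network enrichment as a deterministic graph-grafting
operation. Inputs are a *seed network* (nodes with an identifier
attribute, optional edges) and an ordered list of *RegINs*: directed
regulator → target networks, each from one database release, whose nodes
carry identifiers in one or more identifier systems. The output is a
directed multigraph containing the seed subgraph unchanged plus, for
every qualifying RegIN interaction, one provenance-tagged edge per
supporting RegIN.

Assumptions baked into the model:

* **Exact, case-sensitive identifier matching.** A seed node matches a
  RegIN node iff any of its attribute values string-equals any identifier
  value of the RegIN node. Case folding is deliberately avoided: in
  miRBase nomenclature, case distinguishes a mature miRNA (`hsa-miR-21`)
  from its precursor (`hsa-mir-21`), so folding could merge distinct
  molecules. The cost is that genuinely sloppy-cased inputs will not
  match; the identifier-mapping table is the supported remedy.
* **One-hop extension.** Only original seed nodes are queried; added
  nodes are never re-expanded. Transitive neighbourhoods are obtained by
  re-running with the previous output as the seed. An input that already
  carries the tool's provenance attributes is refused, because re-grafting
  would double-count support.
* **Exactly one provenance tag per added edge.** An interaction found in
  *k* RegINs appears as *k* parallel edges. This keeps "which source says
  so" answerable per edge and makes support equal the parallel-edge count.
* **Direction semantics.** `targets`: the seed node must be the
  interaction's regulator (its downstream targets come in). `regulators`:
  the seed node must be the interaction's target (its upstream regulators
  come in). `both` (default) accepts either; its added-edge set is exactly
  the union of the other two.

## Canonical keys and added-node merging

Added nodes from different RegINs must merge when they denote the same
molecule. Node identity is a *canonical key*: the identifier value of the
first system, in a configurable priority list, that the node carries; a
node carrying none of the priority systems falls back to its
lexicographically smallest identifier value, and an identifier-less node
(which can never match anything) gets a per-RegIN key so it stays
separate. The default priority — Ensembl gene, miRBase accession,
DrugBank, NCBI gene, UniProt, miRBase id — mirrors the per-biotype primary
systems RegIN collections conventionally unify on: Ensembl for genes,
miRBase accessions for miRNAs, DrugBank ids for drugs.

Key-equality merging is deterministic and transitive. The alternative —
merging on *any* shared identifier value — is order-dependent in the
general case (it performs incremental union as RegINs are processed) and
is available as `merge="any-shared-id"` for RegIN collections that
disagree on primary systems; the default stays `canonical`.

Ambiguity is surfaced, never resolved silently: a seed node matching
several RegIN nodes takes the union of their interactions with a
diagnostic; an identifier value shared by several RegIN nodes is noted.

## Support counting and filtering

The support of a (regulator, target) pair is the number of distinct
RegINs with a parallel edge between those canonical endpoints. Two
filters operate purely on visibility flags: per-RegIN hide/show, and the
overlap threshold *k* (an added edge is visible iff its own RegIN is
shown *and* its pair's support ≥ *k*). An added node is visible iff it
retains a visible incident added edge; seed elements are never hidden.
Because state is flags, both filters are fully reversible, and
`export_visible` materialises the filtered graph when a destructive copy
is wanted.

**Support over shown vs loaded sources.** When hide and threshold are
combined, the support of a pair could count hidden RegINs or not. The
default counts only *shown* RegINs, because then any sequence of
hide/threshold operations is equivalent to recomputing visibility from
the final state — the two functions compose predictably. Counting over
all loaded RegINs is available (`support_over="loaded"`) for users who
mean "corroborated by ≥ k sources, shown or not".

## File formats

RegINs and outputs use an XGMML dialect: `att` elements with
`name`/`value`/`type` ∈ {string, integer, real, list}, list members as
nested string `att` children with order preserved; RegIN metadata
(`database`, `version`, `organism`, `type`) as graph-level attributes;
node identifiers as one `identifiers` list attribute of `system:value`
strings (a bare value gets system `unknown`). Documents with or without
the XGMML namespace are accepted; output is namespace-free and
byte-deterministic (insertion order, nodes before edges). One `graph`
element per file; `graphics` subelements are skipped. Seeds may also be
SIF (`source interaction target`) or one-id-per-line node lists, where
the node id doubles as the matching value. All text readers tolerate a
UTF-8 BOM and both line-ending conventions. Style information is carried
only as plain string attributes (`reglink::style` = "grey circle" for
seed nodes, "pink hexagon" for added ones); no renderer is implemented.

Identifier-mapping tables are TSV with a header of system names — the
layout exportable from a BridgeDb mapping database — translated
seed-side only, since RegINs already embed multiple systems per node.
Translations are *added* to a node's matching values; originals are
always retained, so expansion can only widen matching.

## The RegIN builder

`build_regin` converts any tabular interaction dump into a RegIN given a
schema naming the source/target identifier columns (per system), label
columns, evidence columns and metadata. Node identity during building is
the canonical key, so a molecule listed under several labels with one
shared primary id collapses to one node (label collisions are counted and
reported). Multi-valued cells split on a configurable delimiter
(default `|`). Duplicate (source, target) rows collapse to one
interaction with evidence concatenated — both at build time and again at
load time — because one edge per RegIN per pair is what makes support
equal the parallel-edge count. Rows missing all source ids or all target
ids are skipped and counted.

## The synthetic generator

Real RegIN collections are built from external database releases and
cannot be redistributed, so tests run on generated data. `generate`
produces a seed network and RegIN collection with controlled shape:
`n_seed_nodes`, `n_regins`, `interactions_per_regin`, an
`overlap_fraction` of interactions duplicated into a second RegIN, a
`direction_mix` (fraction of seed-touching interactions where the seed
molecule is the target rather than the regulator), and a
`distractor_fraction` (default 0.2) of interactions touching no seed
molecule, so extension has true negatives to exclude. Identifiers come
from two fake secondary systems (`sysA`, `sysB`) plus a fake primary
(`sysP`); seed nodes carry a subset of their molecule's identifiers so
matching genuinely crosses systems. Everything is driven by one integer
seed and is reproducible to the byte.

Crucially, the generator records its own ground truth — the expected
added-edge set per direction mode and the per-pair supporting-RegIN sets —
constructively while generating, without calling the linker. Agreement
between `extend` and this record is therefore a real oracle test, and the
test suite adds a second, independently coded brute-force scan oracle on
messier random instances (shared identifier values across molecules,
identifier-less nodes, self-loops) that the constructive generator keeps
clean.

`figure1_toy` is a fixed instance shaped like a standard miRNA workflow:
4 seed miRNAs, two large "predicted" RegINs (40 and 28 interactions), two
small "validated" ones (6 and 3), exactly 5 pairs supported by ≥ 2
RegINs. Its designed numbers (40/28/6/3 added interactions; 9 visible
edges with the predicted RegINs hidden; 5 pairs at threshold 2) are
construction facts of the fixture, convenient for end-to-end checks.

What the generator does **not** emulate: realistic degree distributions
(real miRNA-target databases are heavy-tailed with hub miRNAs), realistic
identifier collision patterns, organism structure, or evidence-quality
variation. Passing tests therefore demonstrate algorithmic correctness of
matching/grafting/filtering, not robustness to the pathologies of any
particular database export; the builder's schema validation and the RegIN
validator are the intended guard rails there.

## Numerical and procedural choices

* Determinism everywhere: RegINs are processed in configuration order
  (directory discovery sorts lexicographically), interactions in file
  order, ambiguous attach lists sorted; fixed inputs give identical
  output graphs including ordering, and the XGMML writer is
  byte-deterministic.
* Per-RegIN `added_nodes` counts a node for the first RegIN (in
  processing order) that introduces it, so per-RegIN node counts sum to
  the total number of added nodes.
* Self-loops (autoregulation) are grafted as loops and flagged in the
  report, not dropped.
* Degenerate inputs degrade to warnings, not crashes: an empty seed or an
  id-attribute absent from every node yields a zero extension with a
  diagnostic; an identifier-less RegIN node loads with a warning and
  simply never matches.
* Problem sizes in the test suite (up to 50 seed nodes, 5 RegINs, 300
  interactions per RegIN, 200 random instances) were chosen so the
  brute-force oracles remain practical while exercising parallel edges,
  cross-RegIN merging and all direction modes.

## Known limitations

* No live identifier-mapping service; mapping is file-based TSV.
* The `any-shared-id` merge is incremental, not a global union-find over
  all RegINs; with three or more RegINs chained by partial identifier
  overlap, merge results can depend on RegIN order.
* `match_seed`'s per-call index build makes repeated ad-hoc matching
  against the same RegIN quadratic in the worst case; `extend` builds the
  index once per RegIN per run, which is the intended entry point.
* XGMML graphics subelements and session-level Cytoscape constructs are
  out of scope; only plain attributes survive round-trips.
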