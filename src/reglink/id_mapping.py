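"""Identifier translation between systems via a cross-reference table.

When the seed network is annotated in a system (say NCBI gene) that a RegIN
does not embed, its identifiers must be translated first.  The table is a
plain TSV whose header row names the identifier systems and whose rows list
synonymous identifiers — the format a BridgeDb derby file exports to.
Many-to-many mappings are preserved as sets; ambiguity is reported, never
resolved silently.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .graph_model import SeedNetwork


@dataclass
class MappingTable:
    """Rows of synonymous identifiers across named identifier systems.

    ``rows[i][j]`` is the identifier of row *i* in system ``systems[j]``,
    or ``""`` when that row has no identifier in that system.
    """

    systems: list[str]
    rows: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.systems)) != len(self.systems):
            raise ValueError(f"duplicate system names in header: {self.systems}")
        for i, row in enumerate(self.rows):
            if len(row) != len(self.systems):
                raise ValueError(
                    f"row {i + 1} has {len(row)} cells, expected {len(self.systems)}"
                )

    def _column(self, system: str) -> int:
        try:
            return self.systems.index(system)
        except ValueError:
            raise ValueError(
                f"unknown system {system!r}; available: {', '.join(self.systems)}"
            ) from None


def load_mapping_table(path: str | Path) -> MappingTable:
    """Read a mapping TSV (header = system names, empty cell = unmapped)."""
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8-sig"
    )
    systems = [str(c) for c in frame.columns]
    rows = [tuple(str(v) for v in row) for row in frame.itertuples(index=False)]
    return MappingTable(systems=systems, rows=rows)


def translate(
    value: str, from_system: str, to_system: str, table: MappingTable
) -> set[str]:
    """All ``to_system`` identifiers synonymous with ``value``.

    The union of the ``to_system`` cells over every row whose
    ``from_system`` cell equals ``value`` (exact, case-sensitive).  Empty
    set when unmapped.  Identity holds: ``translate(v, s, s)`` contains
    ``v`` whenever ``v`` occurs in column ``s``.
    """
    src = table._column(from_system)
    dst = table._column(to_system)
    return {row[dst] for row in table.rows if row[src] == value and row[dst]}


def expand_seed_ids(
    seed: SeedNetwork,
    table: MappingTable | None,
    seed_system: str,
    target_systems: list[str],
) -> tuple[SeedNetwork, dict]:
    """Augment each seed node's matching attribute with translations.

    Every node's ``id_attribute`` becomes a list: the original value(s)
    plus their translations into each target system.  Original values are
    always retained, so expansion never shrinks a node's id set.  With no
    table the seed is returned unchanged.

    Returns (expanded copy, report) where the report counts translated and
    untranslatable values.
    """
    report = {"translated_values": 0, "untranslated_values": 0, "ambiguous_values": 0}
    if table is None:
        return seed, report
    expanded = copy.deepcopy(seed)
    for node_id in expanded.nodes:
        originals = expanded.id_values(node_id)
        if not originals:
            continue
        out: list[str] = list(originals)
        for value in originals:
            hits: set[str] = set()
            for target in target_systems:
                hits |= translate(value, seed_system, target, table)
            hits.discard("")
            if hits:
                report["translated_values"] += 1
                if len(hits) > 1:
                    report["ambiguous_values"] += 1
            else:
                report["untranslated_values"] += 1
            for hit in sorted(hits):
                if hit not in out:
                    out.append(hit)
        expanded.nodes[node_id][expanded.id_attribute] = out
    return expanded, report
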