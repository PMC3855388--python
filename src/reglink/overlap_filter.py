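"""Post-extension filtering: per-RegIN show/hide and the overlap threshold.

The *support* of a regulator -> target pair is the number of distinct
RegINs containing it — in the extended multigraph, the number of parallel
provenance edges between the same endpoints.  The overlap threshold shows
only pairs supported by at least k RegINs; hide/show temporarily removes
whole RegINs.  Both are non-destructive visibility flags and can be applied
and restored on the same network.

By default support is counted over the currently *shown* RegINs, so hiding
a RegIN and then thresholding composes predictably with recomputing from
scratch; pass ``support_over="loaded"`` to count hidden RegINs too.
"""

from __future__ import annotations

from .graph_model import (
    ORIGIN_ADDED,
    ORIGIN_ATTR,
    REGIN_ATTR,
    VISIBLE_ATTR,
    ExtendedNetwork,
)

SupportIndex = dict[tuple[str, str], set[str]]


def build_support_index(
    extended: ExtendedNetwork, visible_only: bool = False
) -> SupportIndex:
    """(canonical regulator key, canonical target key) -> supporting RegINs.

    With ``visible_only`` the edges of hidden RegINs are excluded, so a
    pair supported only by hidden RegINs disappears from the index.
    """
    index: SupportIndex = {}
    for u, v, _k, d in extended.added_edges():
        name = d[REGIN_ATTR]
        if visible_only and not extended.visibility.get(name, True):
            continue
        pair = (extended.node_canonical(u), extended.node_canonical(v))
        index.setdefault(pair, set()).add(name)
    return index


def refresh_visibility(
    extended: ExtendedNetwork, support_over: str = "shown"
) -> ExtendedNetwork:
    """Recompute every element's visibility flag from the filter state.

    An added edge is visible iff its RegIN is shown and its pair's support
    (over shown RegINs, or all loaded ones with ``support_over="loaded"``)
    meets the threshold.  An added node is visible iff it has at least one
    visible incident added edge; seed nodes and edges are never hidden.
    """
    if support_over not in ("shown", "loaded"):
        raise ValueError(f"support_over must be 'shown' or 'loaded', got {support_over!r}")
    support = build_support_index(extended, visible_only=(support_over == "shown"))
    graph = extended.graph
    for u, v, k, d in extended.added_edges():
        name = d[REGIN_ATTR]
        shown = extended.visibility.get(name, True)
        pair = (extended.node_canonical(u), extended.node_canonical(v))
        visible = shown and len(support.get(pair, set())) >= extended.threshold
        graph.edges[u, v, k][VISIBLE_ATTR] = "true" if visible else "false"
    for node in extended.added_nodes():
        incident_visible = any(
            d.get(ORIGIN_ATTR) == ORIGIN_ADDED and d.get(VISIBLE_ATTR) == "true"
            for _, _, d in graph.in_edges(node, data=True)
        ) or any(
            d.get(ORIGIN_ATTR) == ORIGIN_ADDED and d.get(VISIBLE_ATTR) == "true"
            for _, _, d in graph.out_edges(node, data=True)
        )
        graph.nodes[node][VISIBLE_ATTR] = "true" if incident_visible else "false"
    for node in extended.seed_nodes():
        graph.nodes[node][VISIBLE_ATTR] = "true"
    for u, v, k, _d in extended.seed_edges():
        graph.edges[u, v, k][VISIBLE_ATTR] = "true"
    return extended


def set_visibility(
    extended: ExtendedNetwork,
    regin_name: str,
    visible: bool,
    support_over: str = "shown",
) -> ExtendedNetwork:
    """Show or hide one RegIN's edges (reversible)."""
    if regin_name not in extended.visibility:
        raise ValueError(
            f"unknown RegIN {regin_name!r}; loaded: {', '.join(extended.regin_names)}"
        )
    extended.visibility[regin_name] = bool(visible)
    return refresh_visibility(extended, support_over=support_over)


def apply_threshold(
    extended: ExtendedNetwork, k: int, support_over: str = "shown"
) -> ExtendedNetwork:
    """Show only pairs supported by at least k RegINs (k=1 restores all)."""
    if k < 1:
        raise ValueError(f"threshold must be >= 1, got {k}")
    extended.threshold = int(k)
    return refresh_visibility(extended, support_over=support_over)


def visible_pairs(extended: ExtendedNetwork) -> set[tuple[str, str]]:
    """Distinct (regulator, target) canonical pairs with a visible edge."""
    return {
        (extended.node_canonical(u), extended.node_canonical(v))
        for u, v, _k, _d in extended.visible_added_edges()
    }


def export_visible(extended: ExtendedNetwork) -> ExtendedNetwork:
    """Materialise the filtered view: a copy with hidden elements removed."""
    import copy

    out = copy.deepcopy(extended)
    graph = out.graph
    hidden_edges = [
        (u, v, k)
        for u, v, k, d in graph.edges(keys=True, data=True)
        if d.get(VISIBLE_ATTR) == "false"
    ]
    graph.remove_edges_from(hidden_edges)
    hidden_nodes = [
        n for n, d in graph.nodes(data=True) if d.get(VISIBLE_ATTR) == "false"
    ]
    graph.remove_nodes_from(hidden_nodes)
    return out
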