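"""Seed connection by penalty-weighted shortest paths, plus overlays.

The central operation, :func:`connect_seeds`, links a set of seed objects
(e.g. the proteins and compounds implicated by an expression analysis)
into a most-parsimonious subnetwork: for every unordered seed pair it
finds one minimum-cost path through the knowledge graph, where each
traversed relation costs the penalty weight configured for its relation
type, and returns the union of those paths.  Restricting the allowed
relation types and raising penalties steers the search towards the kinds
of evidence the analyst trusts.

The path search is a label-setting Dijkstra written here so that the
tie-break among equal-cost paths is explicit and deterministic: the
lexicographically smallest node-id sequence wins.  Exhaustive path
enumeration and library shortest-path routines serve as independent
oracles in the test suite.

Information layers (:func:`apply_information_layer`) bin a per-node value
(any report view item) into colour/size classes for display; numeric bins
are half-open ``[low, high)``, values below the first breakpoint fall in
the first bin and values at or above the last breakpoint in the last.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Mapping

from lxml import etree

if TYPE_CHECKING:  # pragma: no cover
    from semkb.store import KnowledgeBase, ObjectRef

__all__ = [
    "NetworkError",
    "SearchConfig",
    "Subnetwork",
    "LayerSpec",
    "connect_seeds",
    "expand",
    "apply_information_layer",
    "export_subnetwork_tsv",
    "export_subnetwork_graphml",
]


class NetworkError(ValueError):
    """Invalid search configuration or layer specification."""


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of a seed-connection search.

    ``penalty`` maps relation-type names to strictly positive edge
    weights (default 1.0 per edge); ``max_path_cost`` discards seed-pair
    paths costlier than the bound; ``undirected`` traverses relations in
    both directions (the default — protein interactions are symmetric).
    """

    allowed_relation_types: frozenset[str] = frozenset()
    penalty: Mapping[str, float] = field(default_factory=dict)
    max_path_cost: float | None = None
    undirected: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "allowed_relation_types", frozenset(self.allowed_relation_types)
        )
        object.__setattr__(self, "penalty", dict(self.penalty))
        if not self.allowed_relation_types:
            raise NetworkError("allowed_relation_types must be non-empty")
        for rtype, w in self.penalty.items():
            if not (w > 0):
                raise NetworkError(
                    f"penalty for {rtype!r} must be strictly positive, got {w}"
                )

    def weight(self, relation_type: str) -> float:
        return float(self.penalty.get(relation_type, 1.0))


@dataclass(frozen=True)
class Subnetwork:
    """A set of objects and relations with optional costs and styles."""

    nodes: frozenset = frozenset()
    edges: frozenset = frozenset()  # relation ObjectRefs
    seed_nodes: frozenset = frozenset()
    path_costs: Mapping = field(default_factory=dict)  # frozenset{a,b} -> cost
    styles: Mapping = field(default_factory=dict)  # node -> {channel: bin label}
    associables: tuple = ()  # annotations/contexts attached to the focus

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        object.__setattr__(self, "seed_nodes", frozenset(self.seed_nodes))
        object.__setattr__(self, "path_costs", dict(self.path_costs))
        object.__setattr__(self, "styles", dict(self.styles))
        if not self.seed_nodes <= self.nodes:
            raise NetworkError("seed_nodes must be a subset of nodes")


@dataclass(frozen=True)
class LayerSpec:
    """Maps a per-node view-item value onto colour or size bins."""

    view_item: object  # a semkb.report.ViewItem
    channel: str = "color"
    numeric_breaks: tuple[float, ...] = ()
    bin_labels: tuple[str, ...] = ()
    nominal_map: Mapping[str, str] = field(default_factory=dict)
    missing_bin: str = "missing"

    def __post_init__(self) -> None:
        object.__setattr__(self, "numeric_breaks", tuple(self.numeric_breaks))
        object.__setattr__(self, "bin_labels", tuple(self.bin_labels))
        object.__setattr__(self, "nominal_map", dict(self.nominal_map))
        if self.channel not in ("color", "size"):
            raise NetworkError("channel must be 'color' or 'size'")
        if any(
            b >= a
            for b, a in zip(self.numeric_breaks, self.numeric_breaks[1:])
        ):
            raise NetworkError("numeric_breaks must be strictly increasing")
        if self.numeric_breaks and len(self.bin_labels) != len(self.numeric_breaks) + 1:
            raise NetworkError(
                "need exactly len(numeric_breaks)+1 bin labels "
                f"({len(self.numeric_breaks) + 1}), got {len(self.bin_labels)}"
            )

    def bin_for(self, value) -> str:
        """Assign one bin; numeric bins are half-open [low, high)."""
        if value is None:
            return self.missing_bin
        if self.numeric_breaks and isinstance(value, (int, float)):
            for i, brk in enumerate(self.numeric_breaks):
                if value < brk:
                    return self.bin_labels[i]
            return self.bin_labels[-1]
        return self.nominal_map.get(str(value), self.missing_bin)


def _adjacency(kb: "KnowledgeBase", config: SearchConfig):
    """node -> sorted [(neighbor, weight, relation ref)] over allowed types."""
    adj: dict = {}
    for rel in kb.relations.values():
        if rel.type not in config.allowed_relation_types:
            continue
        w = config.weight(rel.type)
        ref = rel.ref
        pairs = [(rel.source, rel.target)]
        if config.undirected or not kb.model.relation_type(rel.type).directed:
            pairs.append((rel.target, rel.source))
        for a, b in pairs:
            adj.setdefault(a, []).append((b, w, ref))
    for a in adj:
        adj[a].sort(key=lambda e: (e[0].id, e[1], e[2].id))
    return adj


def _best_path(adj, start, goal, bound: float | None):
    """Min-cost path with lexicographic node-id tie-break.

    Returns (cost, node path, edge refs) or None.  Priority items carry
    the node-id sequence so equal-cost paths pop in lexicographic order.
    """
    heap = [(0.0, (start.id,), start, (), ())]
    best: dict = {}
    while heap:
        cost, idseq, node, path_edges, path_nodes = heapq.heappop(heap)
        if bound is not None and cost > bound:
            return None
        if node == goal:
            return cost, path_nodes + (node,), path_edges
        if node in best and best[node] <= (cost, idseq):
            continue
        best[node] = (cost, idseq)
        for nbr, w, edge in adj.get(node, ()):
            if nbr.id in idseq:  # simple paths only
                continue
            heapq.heappush(
                heap,
                (
                    cost + w,
                    idseq + (nbr.id,),
                    nbr,
                    path_edges + (edge,),
                    path_nodes + (node,),
                ),
            )
    return None


def connect_seeds(
    kb: "KnowledgeBase", seeds: Iterable["ObjectRef"], config: SearchConfig
) -> Subnetwork:
    """Connect every seed pair by one minimum-penalty path.

    The result is the union of one optimal path per unordered seed pair;
    ``path_costs`` records each pair's cost, ``math.inf`` for pairs with
    no allowed path (or none within ``max_path_cost``).
    """
    seeds = sorted(set(seeds), key=lambda r: r.id)
    if len(seeds) < 2:
        raise NetworkError("need at least two seed objects")
    for s in seeds:
        if not kb.exists(s):
            raise NetworkError(f"seed {s} does not exist")
    adj = _adjacency(kb, config)
    nodes = set(seeds)
    edges: set = set()
    costs: dict = {}
    for i, a in enumerate(seeds):
        for b in seeds[i + 1 :]:
            found = _best_path(adj, a, b, config.max_path_cost)
            key = frozenset((a, b))
            if found is None:
                costs[key] = math.inf
                continue
            cost, path_nodes, path_edges = found
            costs[key] = cost
            nodes.update(path_nodes)
            edges.update(path_edges)
    return Subnetwork(
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        seed_nodes=frozenset(seeds),
        path_costs=costs,
    )


def expand(
    kb: "KnowledgeBase", subnet: Subnetwork, relation_types: Iterable[str]
) -> Subnetwork:
    """Merge the one-step neighborhood of every node over the given types."""
    relation_types = set(relation_types)
    for rtype in relation_types:
        kb.model.relation_type(rtype)  # raises on unknown type
    nodes = set(subnet.nodes)
    edges = set(subnet.edges)
    for rel in kb.relations.values():
        if rel.type not in relation_types:
            continue
        if rel.source in subnet.nodes or rel.target in subnet.nodes:
            nodes.add(rel.source)
            nodes.add(rel.target)
            edges.add(rel.ref)
    return replace(
        subnet, nodes=frozenset(nodes), edges=frozenset(edges)
    )


def apply_information_layer(
    kb: "KnowledgeBase", subnet: Subnetwork, spec: LayerSpec
) -> Subnetwork:
    """Assign every node exactly one bin on the spec's channel.

    The view item is evaluated per node; nodes yielding no value (or
    nodes the item does not apply to) land in ``missing_bin``.
    """
    from semkb.report import evaluate_view_item  # deferred: avoids cycle

    styles = {}
    for node in sorted(subnet.nodes, key=lambda r: r.id):
        try:
            value = evaluate_view_item(kb, spec.view_item, node)
        except Exception:
            value = None
        if isinstance(value, (list, tuple)):
            value = len(value) if value else None
        styles[node] = {
            **dict(subnet.styles.get(node, {})),
            spec.channel: spec.bin_for(value),
        }
    merged = {**dict(subnet.styles), **styles}
    return replace(subnet, styles=merged)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_subnetwork_tsv(kb: "KnowledgeBase", subnet: Subnetwork) -> tuple[str, str]:
    """(node table, edge table) as TSV text for external viewers."""
    node_lines = ["id\tkind\ttype\tname\tseed\tcolor\tsize"]
    for node in sorted(subnet.nodes, key=lambda r: r.id):
        kind, type_name, name = kb.describe(node)
        style = subnet.styles.get(node, {})
        node_lines.append(
            "\t".join(
                [
                    str(node.id),
                    kind,
                    type_name,
                    name,
                    "yes" if node in subnet.seed_nodes else "no",
                    str(style.get("color", "")),
                    str(style.get("size", "")),
                ]
            )
        )
    edge_lines = ["id\ttype\tsource\ttarget"]
    for ref in sorted(subnet.edges, key=lambda r: r.id):
        rel = kb.relations[ref.id]
        edge_lines.append(
            f"{ref.id}\t{rel.type}\t{rel.source.id}\t{rel.target.id}"
        )
    return "\n".join(node_lines) + "\n", "\n".join(edge_lines) + "\n"


def export_subnetwork_graphml(kb: "KnowledgeBase", subnet: Subnetwork) -> bytes:
    """GraphML-style XML document of the subnetwork (deterministic)."""
    root = etree.Element("graphml")
    graph = etree.SubElement(root, "graph", edgedefault="undirected")
    for node in sorted(subnet.nodes, key=lambda r: r.id):
        kind, type_name, name = kb.describe(node)
        n = etree.SubElement(graph, "node", id=f"n{node.id}")
        etree.SubElement(n, "data", key="kind").text = kind
        etree.SubElement(n, "data", key="type").text = type_name
        etree.SubElement(n, "data", key="name").text = name
        style = subnet.styles.get(node)
        if style:
            for channel in sorted(style):
                etree.SubElement(n, "data", key=channel).text = str(style[channel])
    for ref in sorted(subnet.edges, key=lambda r: r.id):
        rel = kb.relations[ref.id]
        e = etree.SubElement(
            graph,
            "edge",
            id=f"e{ref.id}",
            source=f"n{rel.source.id}",
            target=f"n{rel.target.id}",
        )
        etree.SubElement(e, "data", key="type").text = rel.type
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
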