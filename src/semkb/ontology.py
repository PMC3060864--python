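"""Ontologies as first-class query vocabulary.

An :class:`OntologyGraph` holds the terms of one hierarchical controlled
vocabulary (loaded from OBO 1.2 via :mod:`obonet`) and answers the
transitive-closure questions that power ontology inference in queries:
*descendants* of a term are its transitively more specific terms,
*ancestors* the more general ones.  Only ``is_a`` and ``part_of`` edges
are kept, and both are treated equivalently for inference; obsolete
terms are skipped at load time.  Cycles are a load-time error — closure
semantics stay predictable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
import networkx as nx
import obonet

__all__ = [
    "OntologyError",
    "OntologyTerm",
    "OntologyGraph",
    "load_obo",
    "closure",
    "match_terms",
]

#: Edge labels followed during inference.
INFERENCE_EDGES = ("is_a", "part_of")


class OntologyError(ValueError):
    """Malformed ontology input or an unknown term."""


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term with its labelled parent edges."""

    ontology: str
    term_id: str
    name: str
    parents: tuple[tuple[str, str], ...] = ()  # (parent term_id, edge label)


@dataclass
class OntologyGraph:
    """A loaded, acyclic ontology with parent/child adjacency."""

    name: str
    terms: dict[str, OntologyTerm] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._children: dict[str, list[str]] = {t: [] for t in self.terms}
        for term in self.terms.values():
            for parent_id, _label in term.parents:
                if parent_id not in self.terms:
                    raise OntologyError(
                        f"ontology {self.name!r}: term {term.term_id!r} has "
                        f"unresolved parent {parent_id!r}"
                    )
                self._children[parent_id].append(term.term_id)
        for kids in self._children.values():
            kids.sort()
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent_id, _label in term.parents:
                g.add_edge(term.term_id, parent_id)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(a for a, _b in cycle)
        raise OntologyError(f"ontology {self.name!r} contains a cycle: {path}")

    @property
    def roots(self) -> list[str]:
        """Terms with no parents, sorted by id."""
        return sorted(t.term_id for t in self.terms.values() if not t.parents)

    def term(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise OntologyError(
                f"unknown term {term_id!r} in ontology {self.name!r}"
            ) from None

    def parents_of(self, term_id: str) -> list[str]:
        return sorted(p for p, _label in self.term(term_id).parents)

    def children_of(self, term_id: str) -> list[str]:
        self.term(term_id)
        return list(self._children[term_id])

    # ------------------------------------------------------------------
    def dump_tsv(self) -> str:
        """Serialise as TSV: term_id, name, |-joined ``parent(label)`` edges."""
        lines = ["term_id\tname\tparents"]
        for term_id in sorted(self.terms):
            t = self.terms[term_id]
            edges = "|".join(f"{p}({lab})" for p, lab in t.parents)
            lines.append(f"{term_id}\t{t.name}\t{edges}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, name: str) -> "OntologyGraph":
        terms: dict[str, OntologyTerm] = {}
        rows = [r for r in text.splitlines() if r.strip()][1:]
        for row in rows:
            term_id, term_name, edges = row.split("\t")
            parents = []
            if edges:
                for e in edges.split("|"):
                    pid, lab = e.rsplit("(", 1)
                    parents.append((pid, lab.rstrip(")")))
            terms[term_id] = OntologyTerm(name, term_id, term_name, tuple(parents))
        return cls(name, terms)


def load_obo(stream, name: str) -> OntologyGraph:
    """Load an OBO 1.2 document into an :class:`OntologyGraph`.

    One term per ``[Term]`` stanza; obsolete terms are skipped; only
    ``is_a`` and ``part_of`` edges are kept.  Accepts a file path, a
    text stream or the OBO text itself.
    """
    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)
    try:
        graph = obonet.read_obo(stream, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted parse errors
        raise OntologyError(f"malformed OBO input for {name!r}: {exc}") from exc
    terms: dict[str, OntologyTerm] = {}
    for term_id, data in graph.nodes(data=True):
        parents: list[tuple[str, str]] = []
        for parent in data.get("is_a", []):
            parents.append((parent, "is_a"))
        for rel in data.get("relationship", []):
            label, _, target = rel.partition(" ")
            if label == "part_of" and target:
                parents.append((target, "part_of"))
        terms[term_id] = OntologyTerm(
            ontology=name,
            term_id=term_id,
            name=data.get("name", term_id),
            parents=tuple(sorted(parents)),
        )
    return OntologyGraph(name, terms)


def closure(
    graph: OntologyGraph, term_id: str, direction: str = "descendants"
) -> set[str]:
    """Transitive closure over is_a/part_of, excluding the start term.

    ``descendants`` walks towards more specific terms (children),
    ``ancestors`` towards more general ones (parents).
    """
    if direction not in ("descendants", "ancestors"):
        raise OntologyError(
            f"direction must be 'descendants' or 'ancestors', got {direction!r}"
        )
    graph.term(term_id)
    step = graph.children_of if direction == "descendants" else graph.parents_of
    seen: set[str] = set()
    frontier = [term_id]
    while frontier:
        current = frontier.pop()
        for nxt in step(current):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen


def match_terms(graph: OntologyGraph, pattern: str) -> set[str]:
    """Terms whose name matches the pattern, ``like``-style.

    Semantics: case-insensitive substring match; ``*`` wildcards are
    stripped, so ``*cancer*`` and ``cancer`` are equivalent.  A bare
    ``*`` (empty needle) matches every term.
    """
    needle = pattern.replace("*", "").lower()
    return {
        t.term_id for t in graph.terms.values() if needle in t.name.lower()
    }


def inferred_terms(graph: OntologyGraph, pattern: str | None = None,
                   term_id: str | None = None) -> set[str]:
    """Pattern- or id-selected terms expanded by descendant inference.

    This is the "inferred by" operation queries use: the matched terms
    themselves plus everything transitively below them.
    """
    if (pattern is None) == (term_id is None):
        raise OntologyError("provide exactly one of pattern or term_id")
    heads = match_terms(graph, pattern) if pattern is not None else {term_id}
    if term_id is not None:
        graph.term(term_id)
    out = set(heads)
    for head in heads:
        out |= closure(graph, head, "descendants")
    return out
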