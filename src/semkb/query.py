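"""Structured queries over the knowledge base.

Queries mirror the sentence structure of a query-building wizard:
*"Object to find is a Patient which simultaneously is annotated by
Patient diagnostic data which has GOLD attribute greater than 2 ... and
never is diagnosed with an ontology entry which is inferred by an entry
named like 'cancer'"*.  The abstract syntax is a recursive clause tree:

* ``AnnotatedBy(form, comparisons)`` — an attached annotation instance
  of the form satisfies all comparisons jointly (per instance);
* ``RelatedVia(relation, direction, partner)`` — a relation of the type
  links the object to a partner satisfying the nested clause;
* ``OntologyLinked(relation, ...)`` — a relation links the object to an
  ontology term in the inferred set of a pattern/term (the matched terms
  plus their transitive descendants);
* ``InContext(context_type, name_like)`` — the object is a member of a
  matching context;
* ``HasExperimentValue(format, label_like, comparisons)`` — some
  experiment row for the object satisfies the comparisons;
* ``And`` / ``Or`` / ``Not`` combinators ("simultaneously" is
  conjunction, "never" negates an existential clause);
* ``IsObject(ref)`` — identity test, used by per-row report queries.

Semantics are existential-witness: a clause holds iff a satisfying
witness exists; ``Not`` holds iff none does.  A missing attribute value
fails every comparison — so ``Age > 30`` excludes patients with no
recorded age, and its negation includes them.  Results are ordered by
object id for reproducibility.

Queries serialise as declarative YAML/JSON mappings (:func:`parse_query`
/ :func:`query_to_mapping`) and may carry named variables bound at run
time (:func:`bind_variables`); a :class:`SmartFolder` is a saved query
re-evaluated on demand, never materialised.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import yaml

from semkb.ontology import inferred_terms
from semkb.schema import AttributeDef, DataModel
from semkb.store import KnowledgeBase, ObjectRef

__all__ = [
    "QueryError",
    "VariableRef",
    "Comparison",
    "AnnotatedBy",
    "RelatedVia",
    "OntologyLinked",
    "InContext",
    "HasExperimentValue",
    "And",
    "Or",
    "Not",
    "IsObject",
    "Query",
    "SmartFolder",
    "parse_query",
    "query_to_mapping",
    "bind_variables",
    "evaluate",
    "brute_force_evaluate",
    "evaluate_smart_folder",
]

OPERATORS = ("eq", "ne", "gt", "ge", "lt", "le", "like")
_ORDERING = ("gt", "ge", "lt", "le")


class QueryError(ValueError):
    """Query does not validate against the model, or is not fully bound."""


@dataclass(frozen=True)
class VariableRef:
    """Placeholder for a query variable, replaced by bind_variables."""

    name: str


@dataclass(frozen=True)
class Comparison:
    attribute: str
    operator: str
    value: object

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise QueryError(f"unknown comparison operator {self.operator!r}")


@dataclass(frozen=True)
class AnnotatedBy:
    form: str
    comparisons: tuple[Comparison, ...] = ()


@dataclass(frozen=True)
class RelatedVia:
    relation: str
    direction: str = "any"  # out | in | any
    partner: "Clause | None" = None


@dataclass(frozen=True)
class OntologyLinked:
    relation: str
    name_like: str | None = None
    term_id: str | None = None
    ontology: str | None = None  # restrict to one ontology; None = all attached


@dataclass(frozen=True)
class InContext:
    context_type: str
    name_like: str | None = None


@dataclass(frozen=True)
class HasExperimentValue:
    format: str
    label_like: str | None = None
    comparisons: tuple[Comparison, ...] = ()


@dataclass(frozen=True)
class And:
    clauses: tuple["Clause", ...]


@dataclass(frozen=True)
class Or:
    clauses: tuple["Clause", ...]


@dataclass(frozen=True)
class Not:
    clause: "Clause"


@dataclass(frozen=True)
class IsObject:
    ref: object  # ObjectRef or VariableRef


Clause = Union[
    AnnotatedBy, RelatedVia, OntologyLinked, InContext, HasExperimentValue,
    And, Or, Not, IsObject,
]


@dataclass(frozen=True)
class Query:
    """A validated query: target element type, clause tree, variables."""

    target_type: str
    root: Clause
    variables: Mapping[str, tuple[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", dict(self.variables))


@dataclass(frozen=True)
class SmartFolder:
    """A saved query whose content is recomputed at every evaluation."""

    name: str
    query: Query
    bound_defaults: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bound_defaults", dict(self.bound_defaults))


# ---------------------------------------------------------------------------
# parsing and validation
# ---------------------------------------------------------------------------

def _parse_value(raw):
    if isinstance(raw, Mapping) and set(raw) == {"var"}:
        return VariableRef(raw["var"])
    return raw


def _check_comparison(attr: AttributeDef, comp: Comparison) -> None:
    if comp.operator == "like" and attr.kind not in ("text", "controlled_term"):
        raise QueryError(
            f"operator 'like' requires a text attribute, {comp.attribute!r} "
            f"is {attr.kind}"
        )
    if comp.operator in _ORDERING and attr.kind not in ("integer", "decimal", "date"):
        raise QueryError(
            f"ordering operator {comp.operator!r} requires a numeric or date "
            f"attribute, {comp.attribute!r} is {attr.kind}"
        )


def _parse_comparisons(raw, lookup) -> tuple[Comparison, ...]:
    comps = []
    for item in raw or ():
        comp = Comparison(
            attribute=item["attribute"],
            operator=item.get("op", item.get("operator", "eq")),
            value=_parse_value(item["value"]) if "value" in item else None,
        )
        attr = lookup(comp.attribute)
        _check_comparison(attr, comp)
        comps.append(comp)
    return tuple(comps)


def _form_attr_lookup(model: DataModel, form_name: str):
    form = model.annotation_form(form_name)

    def lookup(attr_name: str) -> AttributeDef:
        def search(f):
            for a in f.attributes:
                if a.name == attr_name:
                    return a
            for sub in f.subforms:
                found = search(sub)
                if found is not None:
                    return found
            return None

        found = search(form)
        if found is None:
            raise QueryError(
                f"form {form_name!r} has no attribute {attr_name!r}"
            )
        return found

    return lookup


def _parse_clause(raw: Mapping, model: DataModel) -> Clause:
    if not isinstance(raw, Mapping) or len(raw) != 1:
        raise QueryError(f"clause must be a single-key mapping, got {raw!r}")
    key, body = next(iter(raw.items()))
    if key in ("all", "and"):
        return And(tuple(_parse_clause(c, model) for c in body))
    if key in ("any", "or"):
        return Or(tuple(_parse_clause(c, model) for c in body))
    if key in ("not", "never"):
        return Not(_parse_clause(body, model))
    if key == "annotated_by":
        form = body["form"]
        model.annotation_form(form)
        return AnnotatedBy(
            form, _parse_comparisons(body.get("has"), _form_attr_lookup(model, form))
        )
    if key == "related_via":
        relation = body["relation"]
        model.relation_type(relation)
        partner = body.get("partner")
        return RelatedVia(
            relation,
            body.get("direction", "any"),
            _parse_clause(partner, model) if partner is not None else None,
        )
    if key == "ontology_linked":
        relation = body["relation"]
        model.relation_type(relation)
        ontology = body.get("ontology")
        if ontology is not None and ontology not in model.ontologies:
            raise QueryError(f"undeclared ontology {ontology!r}")
        if ("name_like" in body) == ("term_id" in body):
            raise QueryError(
                "ontology_linked needs exactly one of name_like or term_id"
            )
        return OntologyLinked(
            relation, body.get("name_like"), body.get("term_id"), ontology
        )
    if key == "in_context":
        ctype = body["context_type"]
        model.context_type(ctype)
        return InContext(ctype, body.get("name_like"))
    if key == "has_experiment_value":
        fmt_name = body["format"]
        fmt = model.experiment_format(fmt_name)
        return HasExperimentValue(
            fmt_name,
            body.get("label_like"),
            _parse_comparisons(body.get("has"), fmt.column),
        )
    if key == "is_object":
        if isinstance(body, Mapping) and set(body) == {"var"}:
            return IsObject(VariableRef(body["var"]))
        if isinstance(body, Mapping) and {"kind", "id"} <= set(body):
            return IsObject(ObjectRef(body["kind"], int(body["id"])))
        raise QueryError(f"is_object needs a var or a kind/id mapping, got {body!r}")
    raise QueryError(f"unknown clause kind {key!r}")


def _clause_variables(clause: Clause) -> set[str]:
    out: set[str] = set()
    if isinstance(clause, (AnnotatedBy, HasExperimentValue)):
        for comp in clause.comparisons:
            if isinstance(comp.value, VariableRef):
                out.add(comp.value.name)
    elif isinstance(clause, RelatedVia) and clause.partner is not None:
        out |= _clause_variables(clause.partner)
    elif isinstance(clause, (And, Or)):
        for c in clause.clauses:
            out |= _clause_variables(c)
    elif isinstance(clause, Not):
        out |= _clause_variables(clause.clause)
    elif isinstance(clause, IsObject) and isinstance(clause.ref, VariableRef):
        out.add(clause.ref.name)
    return out


def parse_query(source, model: DataModel) -> Query:
    """Parse a declarative query file/mapping and validate it.

    ``source`` may be YAML text, a parsed mapping, or an open stream.
    Unknown forms, relations, attributes and operators are rejected with
    the offending name; every variable reference must be declared.
    """
    if hasattr(source, "read"):
        source = source.read()
    data = yaml.safe_load(source) if isinstance(source, (str, bytes)) else source
    if not isinstance(data, Mapping):
        raise QueryError("query source must be a mapping")
    target = data.get("find")
    model.element_type(target)
    root = _parse_clause(data["where"], model)
    variables = {}
    for name, spec in (data.get("variables") or {}).items():
        spec = spec or {}
        variables[name] = (spec.get("kind", "text"), spec.get("default"))
    undeclared = _clause_variables(root) - set(variables) - {"row"}
    if undeclared:
        raise QueryError(
            f"undeclared query variables: {', '.join(sorted(undeclared))}"
        )
    return Query(target, root, variables)


def _comparison_mapping(comp: Comparison) -> dict:
    value = comp.value
    if isinstance(value, VariableRef):
        value = {"var": value.name}
    return {"attribute": comp.attribute, "op": comp.operator, "value": value}


def _clause_mapping(clause: Clause) -> dict:
    if isinstance(clause, And):
        return {"all": [_clause_mapping(c) for c in clause.clauses]}
    if isinstance(clause, Or):
        return {"any": [_clause_mapping(c) for c in clause.clauses]}
    if isinstance(clause, Not):
        return {"not": _clause_mapping(clause.clause)}
    if isinstance(clause, AnnotatedBy):
        return {
            "annotated_by": {
                "form": clause.form,
                "has": [_comparison_mapping(c) for c in clause.comparisons],
            }
        }
    if isinstance(clause, RelatedVia):
        body: dict = {"relation": clause.relation, "direction": clause.direction}
        if clause.partner is not None:
            body["partner"] = _clause_mapping(clause.partner)
        return {"related_via": body}
    if isinstance(clause, OntologyLinked):
        body = {"relation": clause.relation}
        if clause.name_like is not None:
            body["name_like"] = clause.name_like
        if clause.term_id is not None:
            body["term_id"] = clause.term_id
        if clause.ontology is not None:
            body["ontology"] = clause.ontology
        return {"ontology_linked": body}
    if isinstance(clause, InContext):
        body = {"context_type": clause.context_type}
        if clause.name_like is not None:
            body["name_like"] = clause.name_like
        return {"in_context": body}
    if isinstance(clause, HasExperimentValue):
        body = {"format": clause.format}
        if clause.label_like is not None:
            body["label_like"] = clause.label_like
        if clause.comparisons:
            body["has"] = [_comparison_mapping(c) for c in clause.comparisons]
        return {"has_experiment_value": body}
    if isinstance(clause, IsObject):
        if isinstance(clause.ref, VariableRef):
            return {"is_object": {"var": clause.ref.name}}
        return {"is_object": {"kind": clause.ref.kind, "id": clause.ref.id}}
    raise QueryError(f"unknown clause {clause!r}")


def query_to_mapping(query: Query) -> dict:
    """Inverse of :func:`parse_query` (modulo YAML cosmetics)."""
    out = {"find": query.target_type, "where": _clause_mapping(query.root)}
    if query.variables:
        out["variables"] = {
            name: {"kind": kind, "default": default}
            for name, (kind, default) in query.variables.items()
        }
    return out


# ---------------------------------------------------------------------------
# variable binding
# ---------------------------------------------------------------------------

def _check_binding_kind(kind: str, value) -> None:
    ok = True
    if kind == "integer":
        ok = isinstance(value, int) and not isinstance(value, bool)
    elif kind == "decimal":
        ok = isinstance(value, (int, float)) and not isinstance(value, bool)
    elif kind == "text" or kind == "controlled_term":
        ok = isinstance(value, str)
    elif kind == "date":
        ok = isinstance(value, (str, _dt.date))
    elif kind == "object_reference":
        ok = isinstance(value, ObjectRef)
    if not ok:
        raise QueryError(f"binding value {value!r} does not match kind {kind!r}")


def _bind_clause(clause: Clause, values: Mapping[str, object]) -> Clause:
    if isinstance(clause, (AnnotatedBy, HasExperimentValue)):
        comps = tuple(
            replace(c, value=values.get(c.value.name, c.value))
            if isinstance(c.value, VariableRef)
            else c
            for c in clause.comparisons
        )
        return replace(clause, comparisons=comps)
    if isinstance(clause, RelatedVia) and clause.partner is not None:
        return replace(clause, partner=_bind_clause(clause.partner, values))
    if isinstance(clause, And):
        return And(tuple(_bind_clause(c, values) for c in clause.clauses))
    if isinstance(clause, Or):
        return Or(tuple(_bind_clause(c, values) for c in clause.clauses))
    if isinstance(clause, Not):
        return Not(_bind_clause(clause.clause, values))
    if isinstance(clause, IsObject) and isinstance(clause.ref, VariableRef):
        return IsObject(values.get(clause.ref.name, clause.ref))
    return clause


def bind_variables(query: Query, bindings: Mapping[str, object]) -> Query:
    """Replace variable references by literals; defaults fill the gaps."""
    values: dict[str, object] = {}
    for name, (kind, default) in query.variables.items():
        if name in bindings:
            _check_binding_kind(kind, bindings[name])
            values[name] = bindings[name]
        elif default is not None:
            values[name] = default
    for name in bindings:
        if name not in query.variables and name != "row":
            raise QueryError(f"binding for undeclared variable {name!r}")
    if "row" in bindings:
        values["row"] = bindings["row"]
    bound_root = _bind_clause(query.root, values)
    missing = _clause_variables(bound_root)
    if missing:
        raise QueryError(
            "unbound variables without defaults: " + ", ".join(sorted(missing))
        )
    return Query(query.target_type, bound_root, {})


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _like(actual, pattern) -> bool:
    if not isinstance(actual, str) or not isinstance(pattern, str):
        return False
    return pattern.replace("*", "").lower() in actual.lower()


def _compare(op: str, actual, expected) -> bool:
    """Collapsed three-valued logic: a missing value fails everything."""
    if actual is None:
        return False
    if op == "like":
        return _like(actual, expected)
    if isinstance(actual, _dt.date) and isinstance(expected, str):
        try:
            expected = _dt.date.fromisoformat(expected)
        except ValueError:
            return False
    try:
        if op == "eq":
            return actual == expected
        if op == "ne":
            return actual != expected
        if op == "gt":
            return actual > expected
        if op == "ge":
            return actual >= expected
        if op == "lt":
            return actual < expected
        if op == "le":
            return actual <= expected
    except TypeError:
        return False
    return False


def _value_in(values: Mapping, attribute: str):
    """Attribute lookup descending into nested subform mappings."""
    if attribute in values:
        v = values[attribute]
        return None if isinstance(v, Mapping) else v
    for v in values.values():
        if isinstance(v, Mapping):
            found = _value_in(v, attribute)
            if found is not None:
                return found
    return None


def _values_satisfy(values: Mapping, comparisons: Sequence[Comparison]) -> bool:
    return all(
        _compare(c.operator, _value_in(values, c.attribute), c.value)
        for c in comparisons
    )


def _assert_bound(clause: Clause) -> None:
    if _clause_variables(clause):
        raise QueryError(
            "query is not fully bound: "
            + ", ".join(sorted(_clause_variables(clause)))
        )


class _Evaluator:
    """Index-backed clause evaluation (the production path)."""

    def __init__(self, kb: KnowledgeBase):
        self.kb = kb
        self._inferred_cache: dict = {}

    def _inferred_refs(self, clause: OntologyLinked) -> set[ObjectRef]:
        key = (clause.ontology, clause.name_like, clause.term_id)
        if key in self._inferred_cache:
            return self._inferred_cache[key]
        refs: set[ObjectRef] = set()
        names = (
            [clause.ontology]
            if clause.ontology is not None
            else sorted(self.kb.ontologies)
        )
        for name in names:
            graph = self.kb.ontologies[name]
            if clause.term_id is not None:
                if clause.term_id not in graph.terms:
                    continue
                terms = inferred_terms(graph, term_id=clause.term_id)
            else:
                terms = inferred_terms(graph, pattern=clause.name_like)
            for t in terms:
                refs.add(self.kb.term_ref(name, t))
        self._inferred_cache[key] = refs
        return refs

    def satisfies(self, ref: ObjectRef, clause: Clause) -> bool:
        kb = self.kb
        if isinstance(clause, And):
            return all(self.satisfies(ref, c) for c in clause.clauses)
        if isinstance(clause, Or):
            return any(self.satisfies(ref, c) for c in clause.clauses)
        if isinstance(clause, Not):
            return not self.satisfies(ref, clause.clause)
        if isinstance(clause, IsObject):
            return ref == clause.ref
        if isinstance(clause, AnnotatedBy):
            return any(
                _values_satisfy(a.values, clause.comparisons)
                for a in kb.annotations_of(ref, clause.form)
            )
        if isinstance(clause, RelatedVia):
            for rel in kb.relations_of(ref, [clause.relation]):
                partners = []
                if clause.direction in ("out", "any") and rel.source == ref:
                    partners.append(rel.target)
                if clause.direction in ("in", "any") and rel.target == ref:
                    partners.append(rel.source)
                for p in partners:
                    if clause.partner is None or self.satisfies(p, clause.partner):
                        return True
            return False
        if isinstance(clause, OntologyLinked):
            wanted = self._inferred_refs(clause)
            for rel in kb.relations_of(ref, [clause.relation]):
                partner = rel.target if rel.source == ref else rel.source
                if partner in wanted:
                    return True
            return False
        if isinstance(clause, InContext):
            for ctx in kb.contexts_of(ref, clause.context_type):
                if clause.name_like is None or _like(ctx.name, clause.name_like):
                    return True
            return False
        if isinstance(clause, HasExperimentValue):
            for _table, values in kb.experiment_rows_of(
                ref, clause.format, clause.label_like
            ):
                if _values_satisfy(values, clause.comparisons):
                    return True
            return False
        raise QueryError(f"unknown clause {clause!r}")


def evaluate(kb: KnowledgeBase, query: Query) -> list[ObjectRef]:
    """All elements of the target type satisfying the clause, id-ordered."""
    _assert_bound(query.root)
    ev = _Evaluator(kb)
    return [
        e.ref
        for e in kb.elements_of_type(query.target_type)
        if ev.satisfies(e.ref, query.root)
    ]


def evaluate_smart_folder(
    kb: KnowledgeBase, folder: SmartFolder,
    overrides: Mapping[str, object] | None = None,
) -> list[ObjectRef]:
    """Re-evaluate the folder's query now; no caching is observable."""
    bindings = {**folder.bound_defaults, **(overrides or {})}
    return evaluate(kb, bind_variables(folder.query, bindings))


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_evaluate(kb: KnowledgeBase, query: Query) -> list[ObjectRef]:
    """Reference evaluator: exhaustive witness enumeration, no indexes.

    Same contract as :func:`evaluate`; used to cross-check it.  Scans the
    complete annotation/relation/context/experiment collections for every
    candidate and recomputes ontology closures by naive graph walking.
    """
    _assert_bound(query.root)

    def naive_descendant_closure(graph, head: str) -> set[str]:
        out = {head}
        changed = True
        while changed:
            changed = False
            for term in graph.terms.values():
                for parent_id, _label in term.parents:
                    if parent_id in out and term.term_id not in out:
                        out.add(term.term_id)
                        changed = True
        return out

    def inferred_refs(clause: OntologyLinked) -> set[ObjectRef]:
        refs: set[ObjectRef] = set()
        for name, graph in kb.ontologies.items():
            if clause.ontology is not None and name != clause.ontology:
                continue
            if clause.term_id is not None:
                heads = {clause.term_id} if clause.term_id in graph.terms else set()
            else:
                needle = clause.name_like.replace("*", "").lower()
                heads = {
                    t.term_id
                    for t in graph.terms.values()
                    if needle in t.name.lower()
                }
            terms: set[str] = set()
            for head in heads:
                terms |= naive_descendant_closure(graph, head)
            for t in terms:
                refs.add(kb.term_ref(name, t))
        return refs

    def satisfies(ref: ObjectRef, clause: Clause) -> bool:
        if isinstance(clause, And):
            return all(satisfies(ref, c) for c in clause.clauses)
        if isinstance(clause, Or):
            return any(satisfies(ref, c) for c in clause.clauses)
        if isinstance(clause, Not):
            return not satisfies(ref, clause.clause)
        if isinstance(clause, IsObject):
            return ref == clause.ref
        if isinstance(clause, AnnotatedBy):
            return any(
                ref in a.attached_to
                and a.form == clause.form
                and _values_satisfy(a.values, clause.comparisons)
                for a in kb.annotations.values()
            )
        if isinstance(clause, RelatedVia):
            for rel in kb.relations.values():
                if rel.type != clause.relation:
                    continue
                partners = []
                if clause.direction in ("out", "any") and rel.source == ref:
                    partners.append(rel.target)
                if clause.direction in ("in", "any") and rel.target == ref:
                    partners.append(rel.source)
                for p in partners:
                    if clause.partner is None or satisfies(p, clause.partner):
                        return True
            return False
        if isinstance(clause, OntologyLinked):
            wanted = inferred_refs(clause)
            for rel in kb.relations.values():
                if rel.type != clause.relation:
                    continue
                if rel.source == ref and rel.target in wanted:
                    return True
                if rel.target == ref and rel.source in wanted:
                    return True
            return False
        if isinstance(clause, InContext):
            for ctx in kb.contexts.values():
                if (
                    ctx.type == clause.context_type
                    and ref in ctx.members
                    and (clause.name_like is None or _like(ctx.name, clause.name_like))
                ):
                    return True
            return False
        if isinstance(clause, HasExperimentValue):
            for table in kb.experiments.values():
                if table.format != clause.format:
                    continue
                if clause.label_like is not None and not _like(
                    table.label, clause.label_like
                ):
                    continue
                for row_ref, values in table.rows:
                    if row_ref == ref and _values_satisfy(values, clause.comparisons):
                        return True
            return False
        raise QueryError(f"unknown clause {clause!r}")

    out = []
    for element in sorted(kb.elements.values(), key=lambda e: e.id):
        if element.type == query.target_type and satisfies(element.ref, query.root):
            out.append(element.ref)
    return out
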