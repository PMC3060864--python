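"""The knowledge base: typed instances validated against a data model.

A :class:`KnowledgeBase` holds elements (nodes), relations (edges),
annotation instances, experiment tables and contexts, plus any attached
ontologies whose terms become first-class, relatable objects.  Every
mutation is validated against the :class:`~semkb.schema.DataModel`,
appends exactly one audit record, and the full knowledge base can be
reconstructed from its audit trail alone (:func:`replay_audit` — event
sourcing).  Failed operations leave no trace.

Identity is identifier-based: an element may carry any number of
``(namespace, accession)`` pairs, each unique across the whole knowledge
base, and :meth:`KnowledgeBase.resolve_identifier` is the only sanctioned
way to decide whether two source records denote the same entity — names
are display labels, never identity.

The store is held in memory as plain Python structures and persists as a
text archive (model XML + instance tables as TSV + audit log as
JSON-lines); see :meth:`KnowledgeBase.dump` / :meth:`KnowledgeBase.load`.
"""

from __future__ import annotations

import datetime as _dt
import json
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from semkb.network import Subnetwork
from semkb.ontology import OntologyGraph
from semkb.schema import (
    AnnotationFormDef,
    AttributeDef,
    DataModel,
    SchemaError,
    read_model_xml,
    validate_model,
    write_model_xml,
)

__all__ = [
    "StoreError",
    "ObjectRef",
    "Element",
    "Relation",
    "AnnotationInstance",
    "ExperimentTable",
    "Context",
    "AuditRecord",
    "KnowledgeBase",
    "replay_audit",
]


class StoreError(ValueError):
    """A store operation violated a model constraint or an invariant."""


class ObjectRef(NamedTuple):
    """Stable handle to one knowledge-base object."""

    kind: str  # element | relation | annotation | experiment | context | term
    id: int


@dataclass(frozen=True)
class Element:
    id: int
    type: str
    name: str
    identifiers: frozenset[tuple[str, str]] = frozenset()

    @property
    def ref(self) -> ObjectRef:
        return ObjectRef("element", self.id)


@dataclass(frozen=True)
class Relation:
    id: int
    type: str
    source: ObjectRef
    target: ObjectRef

    @property
    def ref(self) -> ObjectRef:
        return ObjectRef("relation", self.id)


@dataclass(frozen=True)
class AnnotationInstance:
    """One filled annotation form, attachable to many objects at once."""

    id: int
    form: str
    values: Mapping[str, object]
    attached_to: frozenset[ObjectRef]

    @property
    def ref(self) -> ObjectRef:
        return ObjectRef("annotation", self.id)


@dataclass(frozen=True)
class ExperimentTable:
    id: int
    format: str
    label: str
    rows: tuple[tuple[ObjectRef, Mapping[str, object]], ...]

    @property
    def ref(self) -> ObjectRef:
        return ObjectRef("experiment", self.id)


@dataclass(frozen=True)
class Context:
    id: int
    type: str
    name: str
    members: frozenset[ObjectRef]

    @property
    def ref(self) -> ObjectRef:
        return ObjectRef("context", self.id)


@dataclass(frozen=True)
class AuditRecord:
    """One logged mutation; the payload is a full JSON-safe snapshot."""

    seq: int
    timestamp: float
    action: str  # create | update | delete | attach | detach
    payload: Mapping[str, object]


# -- JSON-safe encoding of payload values -----------------------------------

def _enc(value):
    if isinstance(value, ObjectRef):
        return {"__ref__": [value.kind, value.id]}
    if isinstance(value, _dt.date):
        return {"__date__": value.isoformat()}
    if isinstance(value, dict):
        return {k: _enc(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_enc(v) for v in value]
    return value


def _dec(value):
    if isinstance(value, dict):
        if "__ref__" in value and len(value) == 1:
            kind, oid = value["__ref__"]
            return ObjectRef(kind, oid)
        if "__date__" in value and len(value) == 1:
            return _dt.date.fromisoformat(value["__date__"])
        return {k: _dec(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_dec(v) for v in value]
    return value


class KnowledgeBase:
    """Instance store over one data model, with a replayable audit trail."""

    def __init__(self, model: DataModel):
        violations = validate_model(model)
        if violations:
            raise StoreError(
                "cannot open a knowledge base on an invalid model: "
                + "; ".join(str(v) for v in violations)
            )
        self.model = model
        self.elements: dict[int, Element] = {}
        self.relations: dict[int, Relation] = {}
        self.annotations: dict[int, AnnotationInstance] = {}
        self.experiments: dict[int, ExperimentTable] = {}
        self.contexts: dict[int, Context] = {}
        self.terms: dict[int, tuple[str, str]] = {}  # id -> (ontology, term_id)
        self.ontologies: dict[str, OntologyGraph] = {}
        self.audit: list[AuditRecord] = []
        self._next_id = 1
        # secondary indexes
        self._identifier_index: dict[tuple[str, str], int] = {}
        self._triple_index: dict[tuple, int] = {}
        self._term_ref_index: dict[tuple[str, str], ObjectRef] = {}
        self._relations_by_endpoint: dict[ObjectRef, set[int]] = {}
        self._annotations_by_target: dict[ObjectRef, set[int]] = {}
        self._contexts_by_member: dict[ObjectRef, set[int]] = {}
        self._experiments_by_element: dict[ObjectRef, set[int]] = {}

    # ------------------------------------------------------------------
    # resolution helpers
    # ------------------------------------------------------------------
    def exists(self, ref: ObjectRef) -> bool:
        pools = {
            "element": self.elements,
            "relation": self.relations,
            "annotation": self.annotations,
            "experiment": self.experiments,
            "context": self.contexts,
            "term": self.terms,
        }
        return ref.kind in pools and ref.id in pools[ref.kind]

    def get(self, ref: ObjectRef):
        if not self.exists(ref):
            raise StoreError(f"dangling reference {ref}")
        pool = getattr(self, ref.kind + "s")
        return pool[ref.id]

    def type_of(self, ref: ObjectRef) -> str:
        """The model-level type name an endpoint constraint sees."""
        obj = self.get(ref)
        if ref.kind == "element":
            return obj.type
        if ref.kind == "relation":
            return obj.type
        if ref.kind == "annotation":
            return obj.form
        if ref.kind == "context":
            return obj.type
        if ref.kind == "experiment":
            return obj.format
        return obj[0]  # term: its ontology name

    def describe(self, ref: ObjectRef) -> tuple[str, str, str]:
        """(kind, type name, display name) for exports and reports."""
        obj = self.get(ref)
        if ref.kind == "term":
            ontology, term_id = obj
            return "term", ontology, self.ontologies[ontology].term(term_id).name
        name = getattr(obj, "name", getattr(obj, "label", ""))
        return ref.kind, self.type_of(ref), name

    def resolve_identifier(self, namespace: str, accession: str) -> ObjectRef | None:
        oid = self._identifier_index.get((namespace, accession))
        return ObjectRef("element", oid) if oid is not None else None

    def term_ref(self, ontology: str, term_id: str) -> ObjectRef:
        try:
            return self._term_ref_index[(ontology, term_id)]
        except KeyError:
            raise StoreError(
                f"term {term_id!r} of ontology {ontology!r} is not attached"
            ) from None

    # ------------------------------------------------------------------
    # internal audit plumbing
    # ------------------------------------------------------------------
    def _log(self, action: str, payload: Mapping) -> None:
        self.audit.append(
            AuditRecord(
                seq=len(self.audit) + 1,
                timestamp=time.time(),
                action=action,
                payload=_enc(payload),
            )
        )

    def _take_id(self) -> int:
        oid = self._next_id
        self._next_id += 1
        return oid

    # ------------------------------------------------------------------
    # mutations
    # ------------------------------------------------------------------
    def create_element(
        self,
        type: str,
        name: str,
        identifiers: Iterable[tuple[str, str]] = (),
        _id: int | None = None,
    ) -> ObjectRef:
        """Create one element; ``identifiers`` claim KB-wide uniqueness."""
        self.model.element_type(type)
        identifiers = frozenset((str(ns), str(acc)) for ns, acc in identifiers)
        for pair in sorted(identifiers):
            owner = self._identifier_index.get(pair)
            if owner is not None:
                existing = self.elements[owner]
                raise StoreError(
                    f"identifier {pair} already claimed by element "
                    f"{existing.name!r} (id {owner}, type {existing.type!r})"
                )
        oid = self._claim_id(_id)
        element = Element(oid, type, name, identifiers)
        self.elements[oid] = element
        for pair in identifiers:
            self._identifier_index[pair] = oid
        self._log(
            "create",
            {
                "kind": "element",
                "id": oid,
                "type": type,
                "name": name,
                "identifiers": sorted(identifiers),
            },
        )
        return element.ref

    def add_identifiers(
        self, ref: ObjectRef, identifiers: Iterable[tuple[str, str]]
    ) -> None:
        """Extend an element's identifier set (iterative re-mapping rounds)."""
        element = self.get(ref)
        if ref.kind != "element":
            raise StoreError("identifiers attach to elements only")
        new = frozenset((str(ns), str(acc)) for ns, acc in identifiers) - element.identifiers
        if not new:
            return
        for pair in sorted(new):
            owner = self._identifier_index.get(pair)
            if owner is not None and owner != ref.id:
                raise StoreError(
                    f"identifier {pair} already claimed by element id {owner}"
                )
        updated = replace(element, identifiers=element.identifiers | new)
        self.elements[ref.id] = updated
        for pair in new:
            self._identifier_index[pair] = ref.id
        self._log(
            "update",
            {
                "kind": "element",
                "id": ref.id,
                "type": updated.type,
                "name": updated.name,
                "identifiers": sorted(updated.identifiers),
            },
        )

    def create_relation(
        self, type: str, source: ObjectRef, target: ObjectRef, _id: int | None = None
    ) -> ObjectRef:
        """Create one typed edge; duplicate (type, source, target) rejected."""
        rtd = self.model.relation_type(type)
        for endpoint, allowed, side in (
            (source, rtd.source_types, "source"),
            (target, rtd.target_types, "target"),
        ):
            if not self.exists(endpoint):
                raise StoreError(f"{side} endpoint {endpoint} does not exist")
            tname = self.type_of(endpoint)
            if allowed and tname not in allowed:
                raise StoreError(
                    f"relation type {type!r} does not allow {side} of type "
                    f"{tname!r} (constraint: {sorted(allowed)})"
                )
        key = self._triple_key(type, source, target)
        if key in self._triple_index:
            raise StoreError(
                f"duplicate relation {type!r} between {source} and {target}"
            )
        oid = self._claim_id(_id)
        relation = Relation(oid, type, source, target)
        self.relations[oid] = relation
        self._triple_index[key] = oid
        for endpoint in (source, target):
            self._relations_by_endpoint.setdefault(endpoint, set()).add(oid)
        self._log(
            "create",
            {
                "kind": "relation",
                "id": oid,
                "type": type,
                "source": source,
                "target": target,
            },
        )
        return relation.ref

    def _triple_key(self, type: str, source: ObjectRef, target: ObjectRef):
        if not self.model.relation_type(type).directed:
            a, b = sorted((source, target))
            return (type, a, b)
        return (type, source, target)

    def find_relation(
        self, type: str, source: ObjectRef, target: ObjectRef
    ) -> ObjectRef | None:
        oid = self._triple_index.get(self._triple_key(type, source, target))
        return ObjectRef("relation", oid) if oid is not None else None

    # -- annotation values ---------------------------------------------
    def _check_value(self, attr: AttributeDef, value) -> object:
        kind = attr.kind
        if kind == "text":
            if not isinstance(value, str):
                raise StoreError(f"attribute {attr.name!r}: expected text, got {value!r}")
        elif kind == "integer":
            if isinstance(value, bool) or not isinstance(value, int):
                raise StoreError(
                    f"attribute {attr.name!r}: expected integer, got {value!r}"
                )
        elif kind == "decimal":
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise StoreError(
                    f"attribute {attr.name!r}: expected decimal, got {value!r}"
                )
            value = float(value)
        elif kind == "date":
            if isinstance(value, str):
                try:
                    value = _dt.date.fromisoformat(value)
                except ValueError:
                    raise StoreError(
                        f"attribute {attr.name!r}: expected ISO date, got {value!r}"
                    ) from None
            elif not isinstance(value, _dt.date):
                raise StoreError(f"attribute {attr.name!r}: expected date, got {value!r}")
        elif kind == "controlled_term":
            if not isinstance(value, str):
                raise StoreError(
                    f"attribute {attr.name!r}: expected controlled term, got {value!r}"
                )
            if attr.allowed_values is not None and value not in attr.allowed_values:
                raise StoreError(
                    f"attribute {attr.name!r}: {value!r} not in allowed values "
                    f"{list(attr.allowed_values)}"
                )
        elif kind == "object_reference":
            if not isinstance(value, ObjectRef) or not self.exists(value):
                raise StoreError(
                    f"attribute {attr.name!r}: expected an existing object "
                    f"reference, got {value!r}"
                )
        return value

    def _check_form_values(
        self, form: AnnotationFormDef, values: Mapping[str, object]
    ) -> dict:
        subform_names = {f.name: f for f in form.subforms}
        checked: dict[str, object] = {}
        for key, value in values.items():
            if key in subform_names:
                if not isinstance(value, Mapping):
                    raise StoreError(
                        f"subform {key!r} of form {form.name!r} expects a mapping"
                    )
                checked[key] = self._check_form_values(subform_names[key], value)
            else:
                checked[key] = self._check_value(form.attribute(key), value)
        for attr in form.attributes:
            if attr.required and attr.name not in checked:
                raise StoreError(
                    f"form {form.name!r}: required attribute {attr.name!r} missing"
                )
        return checked

    def _form_applicable(self, form: AnnotationFormDef, ref: ObjectRef) -> bool:
        # empty applicable_to means unrestricted
        return not form.applicable_to or self.type_of(ref) in form.applicable_to

    def attach_annotation(
        self,
        form: str,
        values: Mapping[str, object],
        targets: Iterable[ObjectRef],
        _id: int | None = None,
    ) -> ObjectRef:
        """Attach one shared annotation instance to all targets."""
        fdef = self.model.annotation_form(form)
        targets = frozenset(targets)
        if not targets:
            raise StoreError("annotation needs at least one target object")
        for t in sorted(targets):
            if not self.exists(t):
                raise StoreError(f"annotation target {t} does not exist")
            if t.kind == "experiment":
                raise StoreError("annotations do not attach to experiment tables")
            if not self._form_applicable(fdef, t):
                raise StoreError(
                    f"form {form!r} is not applicable to objects of type "
                    f"{self.type_of(t)!r}"
                )
        checked = self._check_form_values(fdef, values)
        oid = self._claim_id(_id)
        ann = AnnotationInstance(oid, form, checked, targets)
        self.annotations[oid] = ann
        for t in targets:
            self._annotations_by_target.setdefault(t, set()).add(oid)
        self._log(
            "attach",
            {
                "kind": "annotation",
                "id": oid,
                "form": form,
                "values": checked,
                "attached_to": sorted(targets),
            },
        )
        return ann.ref

    def record_experiment(
        self,
        format: str,
        label: str,
        rows: Sequence[tuple[ObjectRef, Mapping[str, object]]],
        _id: int | None = None,
    ) -> ObjectRef:
        """Store one experiment table; rows are keyed by typed elements."""
        fmt = self.model.experiment_format(format)
        checked_rows = []
        for ref, values in rows:
            if not self.exists(ref) or ref.kind != "element":
                raise StoreError(f"experiment row references non-element {ref}")
            if self.elements[ref.id].type != fmt.entity_type:
                raise StoreError(
                    f"experiment format {format!r} expects rows of element type "
                    f"{fmt.entity_type!r}, got {self.elements[ref.id].type!r}"
                )
            checked = {}
            for col, value in values.items():
                checked[col] = self._check_value(fmt.column(col), value)
            for col in fmt.columns:
                if col.required and col.name not in checked:
                    raise StoreError(
                        f"format {format!r}: required column {col.name!r} missing"
                    )
            checked_rows.append((ref, checked))
        oid = self._claim_id(_id)
        table = ExperimentTable(oid, format, label, tuple(checked_rows))
        self.experiments[oid] = table
        for ref, _v in checked_rows:
            self._experiments_by_element.setdefault(ref, set()).add(oid)
        self._log(
            "create",
            {
                "kind": "experiment",
                "id": oid,
                "format": format,
                "label": label,
                "rows": [[ref, dict(values)] for ref, values in checked_rows],
            },
        )
        return table.ref

    def build_context(
        self,
        type: str,
        name: str,
        members: Iterable[ObjectRef],
        _id: int | None = None,
    ) -> ObjectRef:
        """Group elements/relations into a named sub-network.

        A relation member's endpoints need not be members themselves —
        pathway definitions cite interactions, not full molecule sets.
        """
        self.model.context_type(type)
        members = frozenset(members)
        for m in sorted(members):
            if not self.exists(m):
                raise StoreError(f"context member {m} does not exist")
        oid = self._claim_id(_id)
        ctx = Context(oid, type, name, members)
        self.contexts[oid] = ctx
        for m in members:
            self._contexts_by_member.setdefault(m, set()).add(oid)
        self._log(
            "create",
            {
                "kind": "context",
                "id": oid,
                "type": type,
                "name": name,
                "members": sorted(members),
            },
        )
        return ctx.ref

    def extend_context(self, ref: ObjectRef, members: Iterable[ObjectRef]) -> None:
        """Add members to an existing context (one update record)."""
        ctx = self.get(ref)
        if ref.kind != "context":
            raise StoreError(f"{ref} is not a context")
        members = frozenset(members) - ctx.members
        if not members:
            return
        for m in sorted(members):
            if not self.exists(m):
                raise StoreError(f"context member {m} does not exist")
        updated = replace(ctx, members=ctx.members | members)
        self.contexts[ref.id] = updated
        for m in members:
            self._contexts_by_member.setdefault(m, set()).add(ref.id)
        self._log(
            "update",
            {
                "kind": "context",
                "id": ref.id,
                "type": updated.type,
                "name": updated.name,
                "members": sorted(updated.members),
            },
        )

    def attach_ontology(
        self, graph: OntologyGraph, _term_ids: Mapping[str, int] | None = None
    ) -> None:
        """Register a loaded ontology; every term becomes a relatable object."""
        if graph.name not in self.model.ontologies:
            raise StoreError(f"ontology {graph.name!r} is not declared in the model")
        if graph.name in self.ontologies:
            raise StoreError(f"ontology {graph.name!r} is already attached")
        self.ontologies[graph.name] = graph
        assigned: dict[str, int] = {}
        for term_id in sorted(graph.terms):
            oid = self._claim_id(None if _term_ids is None else _term_ids[term_id])
            self.terms[oid] = (graph.name, term_id)
            self._term_ref_index[(graph.name, term_id)] = ObjectRef("term", oid)
            assigned[term_id] = oid
        self._log(
            "attach",
            {
                "kind": "ontology",
                "name": graph.name,
                "tsv": graph.dump_tsv(),
                "term_ids": assigned,
            },
        )

    def _claim_id(self, explicit: int | None) -> int:
        if explicit is None:
            return self._take_id()
        if explicit < self._next_id and any(
            explicit in pool
            for pool in (
                self.elements,
                self.relations,
                self.annotations,
                self.experiments,
                self.contexts,
                self.terms,
            )
        ):
            raise StoreError(f"object id {explicit} already in use")
        self._next_id = max(self._next_id, explicit + 1)
        return explicit

    # ------------------------------------------------------------------
    # deletion (refuses when referenced, unless cascading)
    # ------------------------------------------------------------------
    def _inbound(self, ref: ObjectRef) -> list[ObjectRef]:
        refs: list[ObjectRef] = []
        for oid in self._relations_by_endpoint.get(ref, ()):
            refs.append(ObjectRef("relation", oid))
        for oid in self._annotations_by_target.get(ref, ()):
            refs.append(ObjectRef("annotation", oid))
        for oid in self._contexts_by_member.get(ref, ()):
            refs.append(ObjectRef("context", oid))
        for oid in self._experiments_by_element.get(ref, ()):
            refs.append(ObjectRef("experiment", oid))
        for ann in self.annotations.values():
            if ref in _refs_in_values(ann.values):
                refs.append(ann.ref)
        return sorted(set(refs))

    def delete(self, ref: ObjectRef, force: bool = False) -> None:
        """Delete one object; refuses while inbound references exist.

        With ``force=True`` dependants are cascaded (depth-first), each
        removal logging its own audit record.
        """
        self.get(ref)
        inbound = [r for r in self._inbound(ref) if r != ref]
        if inbound and not force:
            raise StoreError(
                f"cannot delete {ref}: referenced by {inbound[:5]}"
                + ("..." if len(inbound) > 5 else "")
            )
        for dep in inbound:
            if self.exists(dep):
                if dep.kind in ("annotation", "context") and ref not in (
                    self.get(dep).attached_to
                    if dep.kind == "annotation"
                    else self.get(dep).members
                ):
                    self.delete(dep, force=True)
                    continue
                # detach membership instead of deleting the whole container
                if dep.kind == "annotation":
                    ann = self.annotations[dep.id]
                    remaining = ann.attached_to - {ref}
                    if remaining:
                        self.annotations[dep.id] = replace(ann, attached_to=remaining)
                        self._annotations_by_target[ref].discard(dep.id)
                        self._log(
                            "detach",
                            {"kind": "annotation", "id": dep.id, "from": ref,
                             "attached_to": sorted(remaining)},
                        )
                        continue
                    self.delete(dep, force=True)
                elif dep.kind == "context":
                    ctx = self.contexts[dep.id]
                    self.contexts[dep.id] = replace(ctx, members=ctx.members - {ref})
                    self._contexts_by_member[ref].discard(dep.id)
                    self._log(
                        "detach",
                        {"kind": "context", "id": dep.id, "member": ref,
                         "members": sorted(ctx.members - {ref})},
                    )
                else:
                    self.delete(dep, force=True)
        self._remove(ref)

    def _remove(self, ref: ObjectRef) -> None:
        if ref.kind == "element":
            element = self.elements.pop(ref.id)
            for pair in element.identifiers:
                self._identifier_index.pop(pair, None)
        elif ref.kind == "relation":
            rel = self.relations.pop(ref.id)
            self._triple_index.pop(self._triple_key(rel.type, rel.source, rel.target), None)
            for endpoint in (rel.source, rel.target):
                self._relations_by_endpoint.get(endpoint, set()).discard(ref.id)
        elif ref.kind == "annotation":
            ann = self.annotations.pop(ref.id)
            for t in ann.attached_to:
                self._annotations_by_target.get(t, set()).discard(ref.id)
        elif ref.kind == "experiment":
            table = self.experiments.pop(ref.id)
            for row_ref, _v in table.rows:
                self._experiments_by_element.get(row_ref, set()).discard(ref.id)
        elif ref.kind == "context":
            ctx = self.contexts.pop(ref.id)
            for m in ctx.members:
                self._contexts_by_member.get(m, set()).discard(ref.id)
        else:
            raise StoreError(f"cannot delete {ref.kind} objects")
        self._log("delete", {"kind": ref.kind, "id": ref.id})

    # ------------------------------------------------------------------
    # browsing
    # ------------------------------------------------------------------
    def relations_of(self, ref: ObjectRef, types: Iterable[str] | None = None
                     ) -> list[Relation]:
        wanted = set(types) if types is not None else None
        out = [
            self.relations[oid]
            for oid in self._relations_by_endpoint.get(ref, ())
        ]
        if wanted is not None:
            out = [r for r in out if r.type in wanted]
        return sorted(out, key=lambda r: r.id)

    def annotations_of(self, ref: ObjectRef, form: str | None = None
                       ) -> list[AnnotationInstance]:
        out = [
            self.annotations[oid]
            for oid in self._annotations_by_target.get(ref, ())
        ]
        if form is not None:
            out = [a for a in out if a.form == form]
        return sorted(out, key=lambda a: a.id)

    def contexts_of(self, ref: ObjectRef, type: str | None = None) -> list[Context]:
        out = [self.contexts[oid] for oid in self._contexts_by_member.get(ref, ())]
        if type is not None:
            out = [c for c in out if c.type == type]
        return sorted(out, key=lambda c: c.id)

    def experiment_rows_of(
        self, ref: ObjectRef, format: str | None = None, label_like: str | None = None
    ) -> list[tuple[ExperimentTable, Mapping[str, object]]]:
        out = []
        for oid in sorted(self._experiments_by_element.get(ref, ())):
            table = self.experiments[oid]
            if format is not None and table.format != format:
                continue
            if label_like is not None:
                needle = label_like.replace("*", "").lower()
                if needle not in table.label.lower():
                    continue
            for row_ref, values in table.rows:
                if row_ref == ref:
                    out.append((table, values))
        return out

    def elements_of_type(self, type: str) -> list[Element]:
        self.model.element_type(type)
        return sorted(
            (e for e in self.elements.values() if e.type == type),
            key=lambda e: e.id,
        )

    def neighborhood(
        self, focus: ObjectRef, allowed_relations: Iterable[str] | None = None
    ) -> Subnetwork:
        """One browsing step: focus, its direct partners, and associables."""
        if not self.exists(focus):
            raise StoreError(f"focus {focus} does not exist")
        nodes = {focus}
        edges = set()
        for rel in self.relations_of(focus, allowed_relations):
            nodes.add(rel.source)
            nodes.add(rel.target)
            edges.add(rel.ref)
        associables = tuple(
            sorted(
                [a.ref for a in self.annotations_of(focus)]
                + [c.ref for c in self.contexts_of(focus)]
            )
        )
        return Subnetwork(
            nodes=frozenset(nodes),
            edges=frozenset(edges),
            seed_nodes=frozenset({focus}),
            associables=associables,
        )

    # ------------------------------------------------------------------
    # integrity, equality, persistence
    # ------------------------------------------------------------------
    def check_integrity(self) -> list[str]:
        """Full-store audit: every ObjectRef must resolve."""
        issues: list[str] = []
        for rel in self.relations.values():
            for side, endpoint in (("source", rel.source), ("target", rel.target)):
                if not self.exists(endpoint):
                    issues.append(f"relation {rel.id}: dangling {side} {endpoint}")
        for ann in self.annotations.values():
            for t in ann.attached_to:
                if not self.exists(t):
                    issues.append(f"annotation {ann.id}: dangling target {t}")
            for ref in _refs_in_values(ann.values):
                if not self.exists(ref):
                    issues.append(f"annotation {ann.id}: dangling value reference {ref}")
        for ctx in self.contexts.values():
            for m in ctx.members:
                if not self.exists(m):
                    issues.append(f"context {ctx.id}: dangling member {m}")
        for table in self.experiments.values():
            for ref, _v in table.rows:
                if not self.exists(ref):
                    issues.append(f"experiment {table.id}: dangling row element {ref}")
        for pair, oid in self._identifier_index.items():
            if oid not in self.elements:
                issues.append(f"identifier index: {pair} points at missing element {oid}")
            elif pair not in self.elements[oid].identifiers:
                issues.append(f"identifier index: {pair} not carried by element {oid}")
        return issues

    def _state(self):
        return (
            self.model,
            self.elements,
            self.relations,
            {k: (v.form, _freeze(v.values), v.attached_to) for k, v in self.annotations.items()},
            self.experiments,
            self.contexts,
            self.terms,
            sorted(self.ontologies),
            [(r.seq, r.action, json.dumps(r.payload, sort_keys=True)) for r in self.audit],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return self._state() == other._state()

    def dump(self, path) -> None:
        """Write the KB archive: model XML + instance TSVs + audit JSONL."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        (path / "model.xml").write_bytes(write_model_xml(self.model))
        with open(path / "audit.jsonl", "w") as fh:
            for rec in self.audit:
                fh.write(
                    json.dumps(
                        {
                            "seq": rec.seq,
                            "timestamp": rec.timestamp,
                            "action": rec.action,
                            "payload": rec.payload,
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )
        tables = path / "instances"
        tables.mkdir(exist_ok=True)
        with open(tables / "elements.tsv", "w") as fh:
            fh.write("id\ttype\tname\tidentifiers\n")
            for e in sorted(self.elements.values(), key=lambda e: e.id):
                ids = "|".join(f"{ns}:{acc}" for ns, acc in sorted(e.identifiers))
                fh.write(f"{e.id}\t{e.type}\t{e.name}\t{ids}\n")
        with open(tables / "relations.tsv", "w") as fh:
            fh.write("id\ttype\tsource_kind\tsource_id\ttarget_kind\ttarget_id\n")
            for r in sorted(self.relations.values(), key=lambda r: r.id):
                fh.write(
                    f"{r.id}\t{r.type}\t{r.source.kind}\t{r.source.id}"
                    f"\t{r.target.kind}\t{r.target.id}\n"
                )
        with open(tables / "annotations.tsv", "w") as fh:
            fh.write("id\tform\tvalues_json\tattached_to\n")
            for a in sorted(self.annotations.values(), key=lambda a: a.id):
                targets = "|".join(f"{t.kind}:{t.id}" for t in sorted(a.attached_to))
                fh.write(
                    f"{a.id}\t{a.form}\t{json.dumps(_enc(dict(a.values)), sort_keys=True)}"
                    f"\t{targets}\n"
                )
        with open(tables / "experiments.tsv", "w") as fh:
            fh.write("id\tformat\tlabel\telement_id\tvalues_json\n")
            for t in sorted(self.experiments.values(), key=lambda t: t.id):
                for ref, values in t.rows:
                    fh.write(
                        f"{t.id}\t{t.format}\t{t.label}\t{ref.id}"
                        f"\t{json.dumps(_enc(dict(values)), sort_keys=True)}\n"
                    )
        with open(tables / "contexts.tsv", "w") as fh:
            fh.write("id\ttype\tname\tmembers\n")
            for c in sorted(self.contexts.values(), key=lambda c: c.id):
                members = "|".join(f"{m.kind}:{m.id}" for m in sorted(c.members))
                fh.write(f"{c.id}\t{c.type}\t{c.name}\t{members}\n")
        onto_dir = path / "ontologies"
        onto_dir.mkdir(exist_ok=True)
        for name in sorted(self.ontologies):
            safe = name.replace("/", "_").replace(" ", "_")
            (onto_dir / f"{safe}.tsv").write_text(self.ontologies[name].dump_tsv())

    @classmethod
    def load(cls, path) -> "KnowledgeBase":
        """Rebuild a KB from its archive by replaying the audit log."""
        path = Path(path)
        model = read_model_xml((path / "model.xml").read_bytes())
        audit: list[AuditRecord] = []
        with open(path / "audit.jsonl") as fh:
            for line in fh:
                if not line.strip():
                    continue
                data = json.loads(line)
                audit.append(
                    AuditRecord(
                        seq=data["seq"],
                        timestamp=data["timestamp"],
                        action=data["action"],
                        payload=data["payload"],
                    )
                )
        return replay_audit(model, audit)


def _refs_in_values(values) -> set[ObjectRef]:
    out: set[ObjectRef] = set()
    if isinstance(values, ObjectRef):
        out.add(values)
    elif isinstance(values, Mapping):
        for v in values.values():
            out |= _refs_in_values(v)
    elif isinstance(values, (list, tuple)):
        for v in values:
            out |= _refs_in_values(v)
    return out


def _freeze(value):
    if isinstance(value, Mapping):
        return tuple(sorted((k, _freeze(v)) for k, v in value.items()))
    if isinstance(value, (list, tuple)):
        return tuple(_freeze(v) for v in value)
    return value


def replay_audit(model: DataModel, audit: Sequence[AuditRecord]) -> KnowledgeBase:
    """Reconstruct a knowledge base from its ordered audit trail.

    The log must be a prefix-closed, gap-free sequence (seq 1, 2, ...)
    emitted by this store; the result is equal (timestamps excluded) to
    the knowledge base that produced the log.
    """
    kb = KnowledgeBase(model)
    for i, rec in enumerate(audit, start=1):
        if rec.seq != i:
            raise StoreError(
                f"audit log out of order: expected seq {i}, got {rec.seq}"
            )
        payload = _dec(dict(rec.payload))
        kind = payload.get("kind")
        if rec.action == "create" or (rec.action == "attach" and kind == "annotation"):
            if kind == "element":
                kb.create_element(
                    payload["type"],
                    payload["name"],
                    [tuple(p) for p in payload["identifiers"]],
                    _id=payload["id"],
                )
            elif kind == "relation":
                kb.create_relation(
                    payload["type"], payload["source"], payload["target"],
                    _id=payload["id"],
                )
            elif kind == "annotation":
                kb.attach_annotation(
                    payload["form"], payload["values"],
                    [ObjectRef(*t) if isinstance(t, (list, tuple)) else t
                     for t in payload["attached_to"]],
                    _id=payload["id"],
                )
            elif kind == "experiment":
                kb.record_experiment(
                    payload["format"], payload["label"],
                    [(row[0], row[1]) for row in payload["rows"]],
                    _id=payload["id"],
                )
            elif kind == "context":
                kb.build_context(
                    payload["type"], payload["name"], payload["members"],
                    _id=payload["id"],
                )
            else:
                raise StoreError(f"unreplayable create payload kind {kind!r}")
        elif rec.action == "attach" and kind == "ontology":
            graph = OntologyGraph.from_tsv(payload["tsv"], payload["name"])
            kb.attach_ontology(graph, _term_ids=payload["term_ids"])
        elif rec.action == "update" and kind == "element":
            ref = ObjectRef("element", payload["id"])
            kb.add_identifiers(ref, [tuple(p) for p in payload["identifiers"]])
        elif rec.action == "update" and kind == "context":
            ref = ObjectRef("context", payload["id"])
            kb.extend_context(ref, payload["members"])
        elif rec.action == "delete":
            kb._remove(ObjectRef(kind, payload["id"]))
        elif rec.action == "detach":
            oid = payload["id"]
            if kind == "annotation":
                ann = kb.annotations[oid]
                removed = payload["from"]
                kb.annotations[oid] = replace(
                    ann, attached_to=ann.attached_to - {removed}
                )
                kb._annotations_by_target.get(removed, set()).discard(oid)
                kb._log("detach", dict(rec.payload))
            elif kind == "context":
                ctx = kb.contexts[oid]
                removed = payload["member"]
                kb.contexts[oid] = replace(ctx, members=ctx.members - {removed})
                kb._contexts_by_member.get(removed, set()).discard(oid)
                kb._log("detach", dict(rec.payload))
            else:
                raise StoreError(f"unreplayable detach payload kind {kind!r}")
        else:
            raise StoreError(f"unreplayable audit action {rec.action!r}")
    return kb
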