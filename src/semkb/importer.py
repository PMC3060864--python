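"""Declarative import templates: delimited tables into the knowledge base.

A template names the source columns it expects and an ordered list of
mapping operations executed per row: create-or-resolve elements keyed by
``(namespace, accession)`` identifiers, map references to existing
entries (optionally constrained to a required entry type), create typed
relations between the resolved handles, attach evidence annotations,
accumulate experiment rows and context memberships.

Entity resolution is strictly identifier-based: an element is reused iff
it already carries the row's identifier pair, a new instance is created
otherwise, and an identifier found on an element of a *different* type
is a conflict — never silent reuse.  No name-based mapping or name
conflict resolution is ever attempted.

Rows are atomic: a row failing any constraint is skipped whole, with a
reason, and contributes nothing to the store (checked by planning every
mutation before applying any).  Re-running a template on the same table
is idempotent — resolution finds the previous elements, duplicate
relations/annotations/rows are recognised and not recreated.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from semkb.schema import AttributeDef, DataModel, SchemaError
from semkb.store import KnowledgeBase, ObjectRef, StoreError

__all__ = [
    "ImportError_",
    "ImportOperation",
    "ImportTemplate",
    "ImportReport",
    "compile_template",
    "resolve_entity",
    "run_import",
    "read_table",
    "TsvAdapter",
]

OP_KINDS = (
    "make_element",
    "map_by_reference",
    "make_relation",
    "attach_annotation",
    "add_experiment_row",
    "add_to_context",
)


class ImportError_(ValueError):
    """Template does not validate against the model or the source table."""


@dataclass(frozen=True)
class ImportOperation:
    op_kind: str
    parameters: Mapping[str, object]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameters", dict(self.parameters))
        if self.op_kind not in OP_KINDS:
            raise ImportError_(f"unknown import operation {self.op_kind!r}")


@dataclass(frozen=True)
class ImportTemplate:
    name: str
    source_columns: tuple[str, ...]
    operations: tuple[ImportOperation, ...]
    handle_types: Mapping[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_columns", tuple(self.source_columns))
        object.__setattr__(self, "operations", tuple(self.operations))
        object.__setattr__(self, "handle_types", dict(self.handle_types))


@dataclass
class ImportReport:
    """Outcome of one import run; rows_processed = accepted + skipped."""

    rows_processed: int = 0
    accepted: int = 0
    created: dict = field(default_factory=dict)  # category -> count
    mapped_to_existing: int = 0
    skipped: list = field(default_factory=list)  # (row number, reason)

    def _count(self, category: str, n: int = 1) -> None:
        self.created[category] = self.created.get(category, 0) + n


def _value_spec(raw) -> tuple[str, object]:
    """A value source: {"column": name} or {"const": literal}."""
    if isinstance(raw, Mapping) and set(raw) == {"column"}:
        return ("column", raw["column"])
    if isinstance(raw, Mapping) and set(raw) == {"const"}:
        return ("const", raw["const"])
    return ("const", raw)


def compile_template(model: DataModel, template_source) -> ImportTemplate:
    """Parse and validate a declarative template against the model.

    Checks mirror an adaptive wizard: every operation may only use model
    entities applicable to the types produced by earlier operations —
    relation endpoint constraints against handle types, annotation-form
    applicability against the annotated handles, experiment entity types
    against the row element's type.
    """
    if hasattr(template_source, "read"):
        template_source = template_source.read()
    if isinstance(template_source, (str, bytes)) and "\n" not in str(template_source):
        template_source = Path(template_source).read_text()
    data = (
        yaml.safe_load(template_source)
        if isinstance(template_source, (str, bytes))
        else template_source
    )
    columns = tuple(data.get("columns") or ())
    operations: list[ImportOperation] = []
    handle_types: dict[str, str | None] = {}

    def need_column(name, op_kind) -> None:
        if name not in columns:
            raise ImportError_(
                f"{op_kind}: column {name!r} is not in the declared column set"
            )

    def need_handle(name, op_kind) -> str | None:
        if name not in handle_types:
            raise ImportError_(f"{op_kind}: handle {name!r} not produced by an earlier op")
        return handle_types[name]

    def check_value_specs(values, lookup, op_kind) -> None:
        for attr_name, raw in (values or {}).items():
            lookup(attr_name)
            src, ref = _value_spec(raw)
            if src == "column":
                need_column(ref, op_kind)

    for raw_op in data.get("operations") or ():
        kind = raw_op.get("op")
        params = {k: v for k, v in raw_op.items() if k != "op"}
        if kind == "make_element":
            model.element_type(params["type"])
            ident = params.get("identifier") or {}
            need_column(ident["column"], kind)
            if "name_from" in params:
                need_column(params["name_from"], kind)
            handle_types[params["handle"]] = params["type"]
        elif kind == "map_by_reference":
            ref = params.get("reference") or {}
            need_column(ref["column"], kind)
            required = params.get("require_type")
            if required is not None:
                model.element_type(required)
            handle_types[params["handle"]] = required
        elif kind == "make_relation":
            rtd = model.relation_type(params["type"])
            src_type = need_handle(params["source"], kind)
            tgt_type = need_handle(params["target"], kind)
            for side, htype, allowed in (
                ("source", src_type, rtd.source_types),
                ("target", tgt_type, rtd.target_types),
            ):
                if htype is not None and allowed and htype not in allowed:
                    raise ImportError_(
                        f"relation {params['type']!r} is not applicable: {side} "
                        f"handle has type {htype!r}, constraint {sorted(allowed)}"
                    )
            if "handle" in params:
                handle_types[params["handle"]] = params["type"]
        elif kind == "attach_annotation":
            form = model.annotation_form(params["form"])
            for h in params.get("to") or ():
                htype = need_handle(h, kind)
                if (
                    htype is not None
                    and form.applicable_to
                    and htype not in form.applicable_to
                ):
                    raise ImportError_(
                        f"form {params['form']!r} is not applicable to handle "
                        f"{h!r} of type {htype!r}"
                    )
            check_value_specs(params.get("values"), form.attribute, kind)
        elif kind == "add_experiment_row":
            fmt = model.experiment_format(params["format"])
            htype = need_handle(params["element"], kind)
            if htype is not None and htype != fmt.entity_type:
                raise ImportError_(
                    f"experiment format {params['format']!r} expects "
                    f"{fmt.entity_type!r} rows, handle {params['element']!r} "
                    f"has type {htype!r}"
                )
            check_value_specs(params.get("values"), fmt.column, kind)
        elif kind == "add_to_context":
            model.context_type(params["context_type"])
            need_handle(params["member"], kind)
            if "name_from" in params:
                need_column(params["name_from"], kind)
        else:
            raise ImportError_(f"unknown import operation {kind!r}")
        operations.append(ImportOperation(kind, params))
    return ImportTemplate(
        name=data.get("name", "unnamed"),
        source_columns=columns,
        operations=tuple(operations),
        handle_types=handle_types,
    )


def resolve_entity(
    kb: KnowledgeBase, type: str, namespace: str, accession: str
) -> tuple[ObjectRef, bool]:
    """Identifier-based create-or-reuse; never merges on name.

    Returns ``(ref, was_created)``.  An identifier already carried by an
    element of a different type raises a conflict instead of silently
    reusing it.
    """
    kb.model.element_type(type)
    existing = kb.resolve_identifier(namespace, accession)
    if existing is not None:
        owner = kb.get(existing)
        if owner.type != type:
            raise StoreError(
                f"identifier ({namespace}, {accession}) is carried by "
                f"{owner.name!r} of type {owner.type!r}, not {type!r}"
            )
        return existing, False
    ref = kb.create_element(type, accession, [(namespace, accession)])
    return ref, True


def _convert(attr: AttributeDef, raw):
    """Coerce a source-table string to the attribute's declared kind."""
    if raw is None:
        return None
    if attr.kind == "integer":
        return int(str(raw).strip())
    if attr.kind == "decimal":
        return float(str(raw).strip())
    return raw if not isinstance(raw, str) else raw.strip()


def read_table(
    source, delimiter: str = "\t", quotechar: str = '"'
) -> list[dict[str, str]]:
    """Read a delimited text table into a list of row dicts."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = source
    reader = csv.DictReader(
        io.StringIO(text), delimiter=delimiter, quotechar=quotechar
    )
    return [dict(row) for row in reader]


class _RowFailure(Exception):
    def __init__(self, reason: str):
        self.reason = reason


def run_import(
    kb: KnowledgeBase, template: ImportTemplate, table: Sequence[Mapping[str, object]]
) -> ImportReport:
    """Apply the template row by row; each row is atomic.

    ``table`` is a sequence of column → value mappings whose keys must
    cover the template's declared columns (checked before any row runs).
    """
    table = list(table)
    if table:
        missing = set(template.source_columns) - set(table[0])
        if missing:
            raise ImportError_(
                "table is missing declared columns: " + ", ".join(sorted(missing))
            )
    report = ImportReport()
    # experiment rows and context members accumulate across rows
    pending_experiments: dict[tuple[str, str], list] = {}
    pending_contexts: dict[tuple[str, str], list] = {}

    def cell(row, spec):
        src, ref = _value_spec(spec)
        if src == "const":
            return ref
        value = row.get(ref)
        if value is None or (isinstance(value, str) and value == ""):
            return None
        return value

    for row_no, row in enumerate(table, start=1):
        report.rows_processed += 1
        try:
            plan = _plan_row(kb, template, row, cell)
        except _RowFailure as fail:
            report.skipped.append((row_no, fail.reason))
            continue
        _apply_row(kb, plan, report, pending_experiments, pending_contexts)
        report.accepted += 1

    for (format_name, label), rows in sorted(pending_experiments.items()):
        existing_rows = set()
        for t in kb.experiments.values():
            if t.format == format_name and t.label == label:
                for ref, values in t.rows:
                    existing_rows.add((ref, tuple(sorted(values.items()))))
        fresh = [
            (ref, values)
            for ref, values in rows
            if (ref, tuple(sorted(values.items()))) not in existing_rows
        ]
        if fresh:
            kb.record_experiment(format_name, label, fresh)
            report._count("experiment")
    for (ctype, name), members in sorted(pending_contexts.items()):
        existing = [
            c for c in kb.contexts.values() if c.type == ctype and c.name == name
        ]
        if existing:
            before = existing[0].members
            fresh = [m for m in members if m not in before]
            if fresh:
                kb.extend_context(existing[0].ref, fresh)
        else:
            kb.build_context(ctype, name, members)
            report._count("context")
    return report


def _plan_row(kb, template, row, cell):
    """Validate one row fully, mutating nothing; returns apply steps."""
    handles: dict[str, tuple[str, object]] = {}  # handle -> ("ref"/"new", ...)
    planned_pairs: dict[tuple[str, str], str] = {}  # identifier -> handle
    steps: list[tuple] = []

    def handle_type(h) -> str:
        state, payload = handles[h]
        if state == "ref":
            return kb.type_of(payload)
        if state == "relation":
            return payload
        return payload["type"]

    def handle_ref_or_none(h):
        state, payload = handles[h]
        return payload if state == "ref" else None

    for op in template.operations:
        p = op.parameters
        if op.op_kind == "make_element":
            ident = p["identifier"]
            accession = cell(row, {"column": ident["column"]})
            if accession is None:
                raise _RowFailure(
                    f"make_element {p['handle']}: empty identifier column "
                    f"{ident['column']!r}"
                )
            namespace = ident["namespace"]
            accession = str(accession)
            existing = kb.resolve_identifier(namespace, accession)
            if existing is not None:
                owner = kb.get(existing)
                if owner.type != p["type"]:
                    raise _RowFailure(
                        f"identifier ({namespace}, {accession}) belongs to an "
                        f"element of type {owner.type!r}, expected {p['type']!r}"
                    )
                handles[p["handle"]] = ("ref", existing)
                steps.append(("reuse_element", p["handle"]))
            elif (namespace, accession) in planned_pairs:
                handles[p["handle"]] = handles[planned_pairs[(namespace, accession)]]
                steps.append(("alias_element", p["handle"], planned_pairs[(namespace, accession)]))
            else:
                name = cell(row, {"column": p["name_from"]}) if "name_from" in p else accession
                handles[p["handle"]] = (
                    "new",
                    {"type": p["type"], "name": str(name), "pair": (namespace, accession)},
                )
                planned_pairs[(namespace, accession)] = p["handle"]
                steps.append(("create_element", p["handle"]))
        elif op.op_kind == "map_by_reference":
            ref_spec = p["reference"]
            accession = cell(row, {"column": ref_spec["column"]})
            if accession is None:
                raise _RowFailure(
                    f"map_by_reference {p['handle']}: empty reference column"
                )
            namespace = ref_spec["namespace"]
            existing = kb.resolve_identifier(namespace, str(accession))
            if existing is None:
                raise _RowFailure(
                    f"reference ({namespace}, {accession}) resolves to no entry"
                )
            required = p.get("require_type")
            actual = kb.type_of(existing)
            if required is not None and actual != required:
                raise _RowFailure(
                    f"reference ({namespace}, {accession}) points at an entry of "
                    f"type {actual!r}, constrained to target entry type {required!r}"
                )
            handles[p["handle"]] = ("ref", existing)
            steps.append(("reuse_element", p["handle"]))
        elif op.op_kind == "make_relation":
            rtd = kb.model.relation_type(p["type"])
            for side, h, allowed in (
                ("source", p["source"], rtd.source_types),
                ("target", p["target"], rtd.target_types),
            ):
                htype = handle_type(h)
                if allowed and htype not in allowed:
                    raise _RowFailure(
                        f"relation {p['type']!r}: {side} type {htype!r} violates "
                        f"constraint {sorted(allowed)}"
                    )
            if "handle" in p:
                handles[p["handle"]] = ("relation", p["type"])
            steps.append(("create_relation", p["type"], p["source"], p["target"], p.get("handle")))
        elif op.op_kind == "attach_annotation":
            form = kb.model.annotation_form(p["form"])
            values = {}
            for attr_name, spec in (p.get("values") or {}).items():
                raw = cell(row, spec)
                if raw is None:
                    continue
                try:
                    values[attr_name] = _convert(form.attribute(attr_name), raw)
                except (ValueError, SchemaError) as exc:
                    raise _RowFailure(
                        f"annotation {p['form']!r}: malformed value for "
                        f"{attr_name!r}: {exc}"
                    ) from exc
            for attr in form.attributes:
                if attr.required and attr.name not in values:
                    raise _RowFailure(
                        f"annotation {p['form']!r}: required attribute "
                        f"{attr.name!r} missing"
                    )
            for h in p.get("to") or ():
                htype = handle_type(h)
                if form.applicable_to and htype not in form.applicable_to:
                    raise _RowFailure(
                        f"form {p['form']!r} not applicable to type {htype!r}"
                    )
            steps.append(("attach_annotation", p["form"], values, tuple(p.get("to") or ())))
        elif op.op_kind == "add_experiment_row":
            fmt = kb.model.experiment_format(p["format"])
            htype = handle_type(p["element"])
            if htype != fmt.entity_type:
                raise _RowFailure(
                    f"experiment format {p['format']!r} expects rows of type "
                    f"{fmt.entity_type!r}, got {htype!r}"
                )
            values = {}
            for col_name, spec in (p.get("values") or {}).items():
                raw = cell(row, spec)
                if raw is None:
                    continue
                try:
                    values[col_name] = _convert(fmt.column(col_name), raw)
                except (ValueError, SchemaError) as exc:
                    raise _RowFailure(
                        f"experiment {p['format']!r}: malformed value for "
                        f"{col_name!r}: {exc}"
                    ) from exc
            for col in fmt.columns:
                if col.required and col.name not in values:
                    raise _RowFailure(
                        f"experiment {p['format']!r}: required column "
                        f"{col.name!r} missing"
                    )
            label = p.get("label", template.name)
            if isinstance(label, Mapping):
                label = cell(row, label)
            steps.append(("experiment_row", p["format"], str(label), p["element"], values))
        elif op.op_kind == "add_to_context":
            name = (
                cell(row, {"column": p["name_from"]})
                if "name_from" in p
                else p.get("name", template.name)
            )
            if name is None:
                raise _RowFailure("add_to_context: empty context name")
            steps.append(("context_member", p["context_type"], str(name), p["member"]))
    return {"handles": handles, "steps": steps}


def _apply_row(kb, plan, report, pending_experiments, pending_contexts):
    handles = plan["handles"]
    resolved: dict[str, ObjectRef] = {}

    def materialise(h) -> ObjectRef:
        if h in resolved:
            return resolved[h]
        state, payload = handles[h]
        if state == "ref":
            resolved[h] = payload
        else:
            ns, acc = payload["pair"]
            existing = kb.resolve_identifier(ns, acc)  # aliased handle in same row
            if existing is not None:
                resolved[h] = existing
            else:
                resolved[h] = kb.create_element(
                    payload["type"], payload["name"], [payload["pair"]]
                )
                report._count("element")
        return resolved[h]

    relation_handles: dict[str, ObjectRef] = {}
    for step in plan["steps"]:
        kind = step[0]
        if kind == "create_element":
            materialise(step[1])
        elif kind in ("reuse_element", "alias_element"):
            materialise(step[1])
            report.mapped_to_existing += 1
        elif kind == "create_relation":
            _k, rtype, src_h, tgt_h, out_handle = step
            source = relation_handles.get(src_h) or materialise(src_h)
            target = relation_handles.get(tgt_h) or materialise(tgt_h)
            existing = kb.find_relation(rtype, source, target)
            if existing is None:
                ref = kb.create_relation(rtype, source, target)
                report._count("relation")
            else:
                ref = existing
            if out_handle:
                relation_handles[out_handle] = ref
        elif kind == "attach_annotation":
            _k, form, values, to = step
            targets = frozenset(
                relation_handles.get(h) or materialise(h) for h in to
            )
            duplicate = any(
                a.form == form and dict(a.values) == values and a.attached_to == targets
                for a in kb.annotations.values()
            )
            if not duplicate:
                kb.attach_annotation(form, values, targets)
                report._count("annotation")
        elif kind == "experiment_row":
            _k, fmt, label, element_h, values = step
            pending_experiments.setdefault((fmt, label), []).append(
                (materialise(element_h), values)
            )
        elif kind == "context_member":
            _k, ctype, name, member_h = step
            member = relation_handles.get(member_h) or materialise(member_h)
            members = pending_contexts.setdefault((ctype, name), [])
            if member not in members:
                members.append(member)


# ---------------------------------------------------------------------------
# external ("virtual") object adapters
# ---------------------------------------------------------------------------

class TsvAdapter:
    """Reference external-source adapter backed by a local TSV file.

    Implements the read-only adapter contract for virtual semantic
    objects: lookup by identifier, list exposed attributes, search by
    attribute value.  The first column is the accession; records are
    never written back.
    """

    def __init__(self, source, namespace: str):
        rows = read_table(source)
        if not rows:
            raise ImportError_("adapter table is empty")
        self.namespace = namespace
        self._key = next(iter(rows[0]))
        self._records = {str(r[self._key]): dict(r) for r in rows}

    def attributes(self) -> list[str]:
        first = next(iter(self._records.values()))
        return list(first)

    def lookup(self, accession: str) -> Mapping[str, str] | None:
        record = self._records.get(str(accession))
        return dict(record) if record is not None else None

    def search(self, attribute: str, value) -> list[Mapping[str, str]]:
        needle = str(value).replace("*", "").lower()
        return [
            dict(r)
            for r in self._records.values()
            if needle in str(r.get(attribute, "")).lower()
        ]
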