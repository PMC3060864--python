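"""Configurable, nestable reports over knowledge-base objects.

A :class:`ReportDef` names an object type and an ordered list of
:class:`ViewItem` columns.  Each view item draws its value from the data
model — an own annotation attribute, related objects, assigned
annotations, a per-row query result, context memberships or experiment
values — or from a registered computed column (a pure function of the
row object).  Reports defined for one object type can be reused as
nested sub-tables wherever that type appears as related objects in
another report.

Rendering is deterministic: one row per input object in input order,
multi-valued cells ordered by related-object id.  Tables export as TSV
(nested sub-tables flattened: each sub-row becomes one ``|``-separated
token, sub-columns joined by ``", "``) or as XML that preserves the
nesting structurally and round-trips byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from lxml import etree

from semkb.schema import DataModel
from semkb.store import KnowledgeBase, ObjectRef

__all__ = [
    "ReportError",
    "ViewItem",
    "ReportDef",
    "Table",
    "validate_report",
    "render_report",
    "evaluate_view_item",
    "export_report",
    "parse_report_xml",
]

VIEW_SOURCES = (
    "own_attribute",
    "related_objects",
    "assigned_annotation",
    "query_result",
    "context_membership",
    "experiment_values",
    "computed",
)


class ReportError(ValueError):
    """Invalid report definition or rendering request."""


@dataclass(frozen=True)
class ViewItem:
    """One report column: where its value comes from, per row object."""

    label: str
    source: str
    form: str | None = None
    attribute: str | None = None
    relation: str | None = None
    direction: str = "any"
    rendered_by: str | None = None  # nested report name; None = display name
    query: object | None = None  # semkb.query.Query with a 'row' variable
    context_type: str | None = None
    format: str | None = None
    label_like: str | None = None
    column: str | None = None
    restriction: str | None = None  # partner type filter
    aggregate: str = "list"  # list | count
    function: str | None = None  # computed-column registry key

    def __post_init__(self) -> None:
        if self.source not in VIEW_SOURCES:
            raise ReportError(f"unknown view-item source {self.source!r}")
        if self.aggregate not in ("list", "count"):
            raise ReportError(f"aggregate must be list or count, got {self.aggregate!r}")


@dataclass(frozen=True)
class ReportDef:
    """An ordered set of view items for one element type."""

    name: str
    object_type: str
    items: tuple[ViewItem, ...]
    nested: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if not self.items:
            raise ReportError(f"report {self.name!r} needs at least one view item")


@dataclass
class Table:
    """A rendered report: headers plus rows of scalar/list/sub-table cells."""

    name: str
    headers: tuple[str, ...]
    rows: list[list]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Table):
            return NotImplemented
        return (
            self.name == other.name
            and self.headers == other.headers
            and self.rows == other.rows
        )


def validate_report(
    report: ReportDef,
    model: DataModel,
    reports: Mapping[str, ReportDef] | None = None,
    _stack: tuple[str, ...] = (),
) -> None:
    """Check all named model entities exist and nesting is acyclic."""
    reports = reports or {}
    if report.name in _stack:
        raise ReportError(
            "cyclic report nesting: " + " > ".join(_stack + (report.name,))
        )
    model.element_type(report.object_type)
    for item in report.items:
        if item.source == "own_attribute":
            form = model.annotation_form(item.form)
            form.attribute(item.attribute)
        elif item.source == "assigned_annotation":
            model.annotation_form(item.form)
        elif item.source == "related_objects":
            model.relation_type(item.relation)
            if item.rendered_by is not None:
                if item.rendered_by not in reports:
                    raise ReportError(f"unknown nested report {item.rendered_by!r}")
                nested = reports[item.rendered_by]
                if item.restriction and nested.object_type != item.restriction:
                    raise ReportError(
                        f"nested report {nested.name!r} renders "
                        f"{nested.object_type!r}, restriction says {item.restriction!r}"
                    )
                validate_report(nested, model, reports, _stack + (report.name,))
        elif item.source == "context_membership":
            model.context_type(item.context_type)
        elif item.source == "experiment_values":
            fmt = model.experiment_format(item.format)
            fmt.column(item.column)
        elif item.source == "query_result":
            if item.query is None:
                raise ReportError(f"view item {item.label!r} needs a query")


def _partners(kb: KnowledgeBase, ref: ObjectRef, item: ViewItem) -> list[ObjectRef]:
    out = []
    for rel in kb.relations_of(ref, [item.relation]):
        if item.direction in ("out", "any") and rel.source == ref:
            out.append(rel.target)
        if item.direction in ("in", "any") and rel.target == ref:
            out.append(rel.source)
    if item.restriction is not None:
        out = [p for p in out if kb.type_of(p) == item.restriction]
    return sorted(set(out), key=lambda r: r.id)


def _compact(values: Mapping) -> str:
    parts = []
    for key in sorted(values):
        v = values[key]
        if isinstance(v, Mapping):
            parts.append(f"{key}={{{_compact(v)}}}")
        else:
            parts.append(f"{key}={v}")
    return "; ".join(parts)


def evaluate_view_item(
    kb: KnowledgeBase,
    item: ViewItem,
    ref: ObjectRef,
    reports: Mapping[str, ReportDef] | None = None,
    computed: Mapping[str, Callable] | None = None,
):
    """Evaluate one view item for one object.

    Returns a scalar, an ordered list, or a nested :class:`Table`;
    ``aggregate="count"`` collapses list values to their length.
    """
    from semkb.query import bind_variables, evaluate  # deferred: layering

    value: object
    if item.source == "own_attribute":
        value = None
        for ann in kb.annotations_of(ref, item.form):
            if item.attribute in ann.values:
                value = ann.values[item.attribute]
                break
    elif item.source == "assigned_annotation":
        value = [_compact(a.values) for a in kb.annotations_of(ref, item.form)]
    elif item.source == "related_objects":
        partners = _partners(kb, ref, item)
        if item.rendered_by is not None:
            nested = (reports or {})[item.rendered_by]
            return render_report(kb, nested, partners, reports, computed)
        value = [kb.describe(p)[2] for p in partners]
    elif item.source == "query_result":
        bound = bind_variables(item.query, {"row": ref})
        hits = evaluate(kb, bound)
        value = [kb.describe(h)[2] for h in hits]
    elif item.source == "context_membership":
        value = [c.name for c in kb.contexts_of(ref, item.context_type)]
    elif item.source == "experiment_values":
        value = [
            row_values[item.column]
            for _table, row_values in kb.experiment_rows_of(
                ref, item.format, item.label_like
            )
            if item.column in row_values
        ]
    else:  # computed
        registry = computed or {}
        if item.function not in registry:
            raise ReportError(f"no computed column registered as {item.function!r}")
        value = registry[item.function](kb, ref)
    if item.aggregate == "count" and isinstance(value, list):
        return len(value)
    return value


def render_report(
    kb: KnowledgeBase,
    report: ReportDef,
    objects: Sequence[ObjectRef],
    reports: Mapping[str, ReportDef] | None = None,
    computed: Mapping[str, Callable] | None = None,
) -> Table:
    """One row per object, in input order; cells per the view items."""
    validate_report(report, kb.model, reports)
    rows = []
    for ref in objects:
        if kb.type_of(ref) != report.object_type:
            raise ReportError(
                f"report {report.name!r} renders {report.object_type!r} objects, "
                f"got {kb.type_of(ref)!r}"
            )
        rows.append(
            [
                evaluate_view_item(kb, item, ref, reports, computed)
                for item in report.items
            ]
        )
    return Table(report.name, tuple(i.label for i in report.items), rows)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _cell_tsv(cell) -> str:
    if isinstance(cell, Table):
        return "|".join(
            ", ".join(_cell_tsv(c) for c in row) for row in cell.rows
        )
    if isinstance(cell, list):
        return "|".join(str(v) for v in cell)
    return "" if cell is None else str(cell)


def _table_xml(table: Table, parent) -> None:
    node = etree.SubElement(parent, "report", name=table.name)
    columns = etree.SubElement(node, "columns")
    for h in table.headers:
        etree.SubElement(columns, "column", label=h)
    for row in table.rows:
        row_node = etree.SubElement(node, "row")
        for header, cell in zip(table.headers, row):
            cell_node = etree.SubElement(row_node, "cell", label=header)
            if isinstance(cell, Table):
                _table_xml(cell, cell_node)
            elif isinstance(cell, list):
                lst = etree.SubElement(cell_node, "list")
                for v in cell:
                    etree.SubElement(lst, "value").text = str(v)
            elif cell is not None:
                cell_node.text = str(cell)


def export_report(table: Table, format: str = "tsv"):
    """Serialise a rendered table; TSV flattens, XML preserves nesting."""
    if format == "tsv":
        lines = ["\t".join(table.headers)]
        for row in table.rows:
            lines.append("\t".join(_cell_tsv(c) for c in row))
        return "\n".join(lines) + "\n"
    if format == "xml":
        root = etree.Element("report-export")
        _table_xml(table, root)
        return etree.tostring(
            root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
        )
    raise ReportError(f"unknown export format {format!r} (expected tsv or xml)")


def _parse_table(node) -> Table:
    headers = tuple(
        c.get("label") for c in node.find("columns")
    )
    rows = []
    for row_node in node.findall("row"):
        row = []
        for cell in row_node.findall("cell"):
            sub = cell.find("report")
            lst = cell.find("list")
            if sub is not None:
                row.append(_parse_table(sub))
            elif lst is not None:
                row.append([v.text if v.text is not None else "" for v in lst])
            else:
                row.append(cell.text if cell.text is not None else None)
        rows.append(row)
    return Table(node.get("name"), headers, rows)


def view_item_from_mapping(data: Mapping, model: DataModel | None = None) -> ViewItem:
    """Build a ViewItem from a declarative (YAML/JSON) mapping.

    A ``query_result`` item carries its query inline under ``query``,
    parsed and validated when ``model`` is given.
    """
    from semkb.query import parse_query  # deferred: layering

    data = dict(data)
    if "query" in data and data["query"] is not None and model is not None:
        data["query"] = parse_query(data["query"], model)
    return ViewItem(**data)


def report_def_from_mapping(data: Mapping, model: DataModel) -> ReportDef:
    """Build and validate a ReportDef from a declarative mapping."""
    items = tuple(
        view_item_from_mapping(item, model) for item in data.get("items") or ()
    )
    report = ReportDef(
        name=data.get("name", "report"),
        object_type=data["object_type"],
        items=items,
        nested=bool(data.get("nested", True)),
    )
    validate_report(report, model)
    return report


def parse_report_xml(document: bytes | str) -> Table:
    """Parse an XML report export back into a :class:`Table`.

    Values come back as strings; re-exporting the parsed table yields a
    byte-identical document.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    root = etree.fromstring(document)
    report = root.find("report")
    if report is None:
        raise ReportError("document has no <report> node")
    return _parse_table(report)
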