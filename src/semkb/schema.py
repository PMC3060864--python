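"""Project-specific semantic data models.

A :class:`DataModel` declares the vocabulary of a knowledge base: which
element (node) types exist, which relation (edge) types connect them,
which annotation forms and experiment formats can decorate them, which
context (sub-network) types group them, and which ontologies and external
sources participate.  Instances (the actual genes, patients, edges, ...)
live in :mod:`semkb.store` and are validated against the model.

Seven concept categories exist::

    element, relation, annotation_form, experiment_format,
    context, ontology, external_source

Models are immutable: :func:`define_type` returns a new validated model
and never partially applies a failed definition.

XML dialect
-----------
``write_model_xml`` emits one root ``<data-model>`` with one section per
category, one node per definition, scalar fields as XML attributes and
list fields as child nodes; ordering is deterministic (categories in
fixed order, definitions sorted by name) so serialisation is stable.
``read_model_xml`` accepts the same dialect, or a foreign vocabulary via
a declarative :class:`TagProfile` that maps foreign tag and attribute
names onto the dialect, so third-party model exports can be parsed
without code changes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from lxml import etree

__all__ = [
    "CATEGORIES",
    "ATTRIBUTE_KINDS",
    "SchemaError",
    "Violation",
    "AttributeDef",
    "ElementTypeDef",
    "RelationTypeDef",
    "AnnotationFormDef",
    "ExperimentFormatDef",
    "ContextTypeDef",
    "OntologyDef",
    "ExternalSourceDef",
    "DataModel",
    "TagProfile",
    "define_type",
    "validate_model",
    "write_model_xml",
    "read_model_xml",
    "count_definitions",
]

#: The seven fundamental concept categories of a semantic data model.
CATEGORIES = (
    "element",
    "relation",
    "annotation_form",
    "experiment_format",
    "context",
    "ontology",
    "external_source",
)

#: Value kinds an annotation attribute / experiment column may declare.
ATTRIBUTE_KINDS = (
    "text",
    "integer",
    "decimal",
    "date",
    "controlled_term",
    "object_reference",
)


class SchemaError(ValueError):
    """A definition or document violates the data-model contract."""


@dataclass(frozen=True)
class Violation:
    """One broken model invariant: which category, which name, which rule."""

    category: str
    name: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.category}] {self.name!r}: {self.rule}"


def _tuple(items: Iterable) -> tuple:
    return tuple(items) if items is not None else ()


def _frozenset(items: Iterable[str]) -> frozenset:
    return frozenset(items) if items is not None else frozenset()


@dataclass(frozen=True)
class AttributeDef:
    """A typed attribute of an annotation form or experiment format.

    ``allowed_values`` is only meaningful for ``controlled_term`` kinds,
    where it enumerates the permitted vocabulary.
    """

    name: str
    kind: str = "text"
    required: bool = False
    allowed_values: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("attribute name must be non-empty")
        if self.kind not in ATTRIBUTE_KINDS:
            raise SchemaError(
                f"attribute {self.name!r}: unknown kind {self.kind!r} "
                f"(expected one of {', '.join(ATTRIBUTE_KINDS)})"
            )
        if self.allowed_values is not None:
            object.__setattr__(self, "allowed_values", _tuple(self.allowed_values))
            if self.kind != "controlled_term":
                raise SchemaError(
                    f"attribute {self.name!r}: allowed_values only valid for "
                    f"controlled_term attributes, not {self.kind!r}"
                )


@dataclass(frozen=True)
class ElementTypeDef:
    """A basic unit of the knowledge model, e.g. ``Gene`` or ``Patient``."""

    name: str
    description: str = ""


@dataclass(frozen=True)
class RelationTypeDef:
    """A typed, labelled edge between semantic objects.

    ``source_types``/``target_types`` constrain the endpoint types; each
    name must resolve to a declared element type, ontology, context type
    or external source.
    """

    name: str
    source_types: frozenset[str] = frozenset()
    target_types: frozenset[str] = frozenset()
    directed: bool = True
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "source_types", _frozenset(self.source_types))
        object.__setattr__(self, "target_types", _frozenset(self.target_types))


@dataclass(frozen=True)
class AnnotationFormDef:
    """A structured attribute record attachable to semantic objects.

    Forms nest (``subforms``) to organise information hierarchically;
    ``applicable_to`` restricts which object types may carry the form.
    """

    name: str
    attributes: tuple[AttributeDef, ...] = ()
    subforms: tuple["AnnotationFormDef", ...] = ()
    applicable_to: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", _tuple(self.attributes))
        object.__setattr__(self, "subforms", _tuple(self.subforms))
        object.__setattr__(self, "applicable_to", _frozenset(self.applicable_to))

    def attribute(self, name: str) -> AttributeDef:
        for a in self.attributes:
            if a.name == name:
                return a
        raise SchemaError(f"form {self.name!r} has no attribute {name!r}")

    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]


@dataclass(frozen=True)
class ExperimentFormatDef:
    """Tabular high-throughput annotation: rows keyed by one element type."""

    name: str
    entity_type: str = ""
    columns: tuple[AttributeDef, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "columns", _tuple(self.columns))

    def column(self, name: str) -> AttributeDef:
        for c in self.columns:
            if c.name == name:
                return c
        raise SchemaError(f"format {self.name!r} has no column {name!r}")


@dataclass(frozen=True)
class ContextTypeDef:
    """A named kind of sub-network (pathway, disease process, complex)."""

    name: str
    description: str = ""


@dataclass(frozen=True)
class OntologyDef:
    """A hierarchical controlled vocabulary registered with the model."""

    name: str
    source_format: str = "obo"

    def __post_init__(self) -> None:
        if self.source_format not in ("obo", "builtin"):
            raise SchemaError(
                f"ontology {self.name!r}: source_format must be obo or builtin"
            )


@dataclass(frozen=True)
class ExternalSourceDef:
    """A read-only external object source exposed through an adapter."""

    name: str
    adapter_id: str = ""
    exposed_attributes: tuple[AttributeDef, ...] = ()
    writable: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "exposed_attributes", _tuple(self.exposed_attributes))
        if self.writable:
            raise SchemaError(
                f"external source {self.name!r}: external objects are read-only"
            )


_CATEGORY_FIELD = {
    "element": "element_types",
    "relation": "relation_types",
    "annotation_form": "annotation_forms",
    "experiment_format": "experiment_formats",
    "context": "context_types",
    "ontology": "ontologies",
    "external_source": "external_sources",
}

_CATEGORY_CLASS = {
    "element": ElementTypeDef,
    "relation": RelationTypeDef,
    "annotation_form": AnnotationFormDef,
    "experiment_format": ExperimentFormatDef,
    "context": ContextTypeDef,
    "ontology": OntologyDef,
    "external_source": ExternalSourceDef,
}


@dataclass(frozen=True)
class DataModel:
    """The complete meta-model of a project-specific knowledge base."""

    element_types: dict[str, ElementTypeDef] = field(default_factory=dict)
    relation_types: dict[str, RelationTypeDef] = field(default_factory=dict)
    annotation_forms: dict[str, AnnotationFormDef] = field(default_factory=dict)
    experiment_formats: dict[str, ExperimentFormatDef] = field(default_factory=dict)
    context_types: dict[str, ContextTypeDef] = field(default_factory=dict)
    ontologies: dict[str, OntologyDef] = field(default_factory=dict)
    external_sources: dict[str, ExternalSourceDef] = field(default_factory=dict)

    def category(self, category: str) -> dict:
        """The name → definition mapping for one concept category."""
        if category not in _CATEGORY_FIELD:
            raise SchemaError(
                f"unknown concept category {category!r} "
                f"(expected one of {', '.join(CATEGORIES)})"
            )
        return getattr(self, _CATEGORY_FIELD[category])

    # -- convenience lookups used throughout the package ----------------
    def element_type(self, name: str) -> ElementTypeDef:
        try:
            return self.element_types[name]
        except KeyError:
            raise SchemaError(f"undeclared element type {name!r}") from None

    def relation_type(self, name: str) -> RelationTypeDef:
        try:
            return self.relation_types[name]
        except KeyError:
            raise SchemaError(f"undeclared relation type {name!r}") from None

    def annotation_form(self, name: str) -> AnnotationFormDef:
        try:
            return self.annotation_forms[name]
        except KeyError:
            raise SchemaError(f"undeclared annotation form {name!r}") from None

    def experiment_format(self, name: str) -> ExperimentFormatDef:
        try:
            return self.experiment_formats[name]
        except KeyError:
            raise SchemaError(f"undeclared experiment format {name!r}") from None

    def context_type(self, name: str) -> ContextTypeDef:
        try:
            return self.context_types[name]
        except KeyError:
            raise SchemaError(f"undeclared context type {name!r}") from None

    def endpoint_names(self) -> frozenset[str]:
        """All names a relation endpoint constraint may legally reference."""
        return frozenset(self.element_types) | frozenset(self.ontologies) | frozenset(
            self.context_types
        ) | frozenset(self.external_sources)


def _validate_form(
    form: AnnotationFormDef,
    model: DataModel,
    out: list[Violation],
    seen_stack: tuple[str, ...] = (),
) -> None:
    if form.name in seen_stack:
        out.append(
            Violation(
                "annotation_form",
                form.name,
                "cyclic subform nesting: " + " > ".join(seen_stack + (form.name,)),
            )
        )
        return
    names = [a.name for a in form.attributes]
    for name in sorted({n for n in names if names.count(n) > 1}):
        out.append(
            Violation(
                "annotation_form",
                form.name,
                f"duplicate attribute name {name!r} within one form level",
            )
        )
    attachable = (
        frozenset(model.element_types)
        | frozenset(model.relation_types)
        | frozenset(model.annotation_forms)
        | frozenset(model.context_types)
    )
    for t in sorted(form.applicable_to - attachable):
        out.append(
            Violation(
                "annotation_form",
                form.name,
                f"applicable_to references undeclared type {t!r}",
            )
        )
    for sub in form.subforms:
        _validate_form(sub, model, out, seen_stack + (form.name,))


def validate_model(model: DataModel) -> list[Violation]:
    """Check every model invariant; violations are data, not exceptions."""
    out: list[Violation] = []
    known_endpoints = model.endpoint_names()
    for rel in model.relation_types.values():
        for t in sorted((rel.source_types | rel.target_types) - known_endpoints):
            out.append(
                Violation(
                    "relation",
                    rel.name,
                    f"endpoint constraint references undeclared type {t!r}",
                )
            )
        if not rel.source_types or not rel.target_types:
            out.append(
                Violation(
                    "relation", rel.name, "source_types and target_types must be non-empty"
                )
            )
    for form in model.annotation_forms.values():
        _validate_form(form, model, out)
    for fmt in model.experiment_formats.values():
        if fmt.entity_type not in model.element_types:
            out.append(
                Violation(
                    "experiment_format",
                    fmt.name,
                    f"entity_type {fmt.entity_type!r} is not a declared element type",
                )
            )
        if not fmt.columns:
            out.append(
                Violation("experiment_format", fmt.name, "must declare at least one column")
            )
    return out


def define_type(model: DataModel, category: str, definition) -> DataModel:
    """Return a new model containing ``definition``; the input is unchanged.

    Rejects duplicate names within the category (naming the clash) and
    definitions whose cross-references do not resolve (listing the
    unresolved names); a failed definition leaves no trace.
    """
    current = model.category(category)
    expected = _CATEGORY_CLASS[category]
    if not isinstance(definition, expected):
        raise SchemaError(
            f"category {category!r} expects a {expected.__name__}, "
            f"got {type(definition).__name__}"
        )
    if not definition.name:
        raise SchemaError(f"{category} definition must have a non-empty name")
    if definition.name in current:
        raise SchemaError(
            f"duplicate {category} name {definition.name!r}: already defined"
        )
    candidate = replace(
        model,
        **{
            _CATEGORY_FIELD[category]: {
                **current,
                definition.name: definition,
            }
        },
    )
    violations = validate_model(candidate)
    fresh = [v for v in violations if v not in validate_model(model)]
    if fresh:
        raise SchemaError(
            f"cannot add {category} {definition.name!r}: "
            + "; ".join(str(v) for v in fresh)
        )
    return candidate


def count_definitions(model: DataModel, category: str) -> int:
    """Exact number of definitions in one concept category."""
    return len(model.category(category))


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------

_SECTION_TAG = {
    "element": "element-types",
    "relation": "relation-types",
    "annotation_form": "annotation-forms",
    "experiment_format": "experiment-formats",
    "context": "context-types",
    "ontology": "ontologies",
    "external_source": "external-sources",
}
_ITEM_TAG = {
    "element": "element-type",
    "relation": "relation-type",
    "annotation_form": "annotation-form",
    "experiment_format": "experiment-format",
    "context": "context-type",
    "ontology": "ontology",
    "external_source": "external-source",
}


def _bool(v: bool) -> str:
    return "true" if v else "false"


def _parse_bool(v: str | None, default: bool) -> bool:
    if v is None:
        return default
    return v.strip().lower() in ("true", "1", "yes")


def _attr_node(parent, tag: str, a: AttributeDef) -> None:
    node = etree.SubElement(parent, tag, name=a.name, kind=a.kind, required=_bool(a.required))
    if a.allowed_values is not None:
        for v in a.allowed_values:
            etree.SubElement(node, "allowed", value=v)


def _form_node(parent, form: AnnotationFormDef, tag: str = "annotation-form") -> None:
    node = etree.SubElement(parent, tag, name=form.name)
    for t in sorted(form.applicable_to):
        etree.SubElement(node, "applies-to", type=t)
    for a in form.attributes:
        _attr_node(node, "attribute", a)
    for sub in form.subforms:
        _form_node(node, sub, "subform")


def write_model_xml(model: DataModel) -> bytes:
    """Serialise a validated model to the package's XML dialect.

    Output is deterministic for a given model: stable category order,
    definitions sorted by name, endpoint sets sorted.
    """
    violations = validate_model(model)
    if violations:
        raise SchemaError(
            "refusing to serialise an invalid model: "
            + "; ".join(str(v) for v in violations)
        )
    root = etree.Element("data-model")
    for category in CATEGORIES:
        section = etree.SubElement(root, _SECTION_TAG[category])
        for name in sorted(model.category(category)):
            d = model.category(category)[name]
            if category == "element":
                etree.SubElement(
                    section, "element-type", name=d.name, description=d.description
                )
            elif category == "relation":
                node = etree.SubElement(
                    section,
                    "relation-type",
                    name=d.name,
                    directed=_bool(d.directed),
                    description=d.description,
                )
                for t in sorted(d.source_types):
                    etree.SubElement(node, "source", type=t)
                for t in sorted(d.target_types):
                    etree.SubElement(node, "target", type=t)
            elif category == "annotation_form":
                _form_node(section, d)
            elif category == "experiment_format":
                node = etree.SubElement(
                    section,
                    "experiment-format",
                    name=d.name,
                    **{"entity-type": d.entity_type},
                )
                for c in d.columns:
                    _attr_node(node, "column", c)
            elif category == "context":
                etree.SubElement(
                    section, "context-type", name=d.name, description=d.description
                )
            elif category == "ontology":
                etree.SubElement(
                    section,
                    "ontology",
                    name=d.name,
                    **{"source-format": d.source_format},
                )
            elif category == "external_source":
                node = etree.SubElement(
                    section,
                    "external-source",
                    name=d.name,
                    **{"adapter-id": d.adapter_id},
                )
                for a in d.exposed_attributes:
                    _attr_node(node, "attribute", a)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


@dataclass(frozen=True)
class TagProfile:
    """Declarative mapping from a foreign XML vocabulary onto the dialect.

    ``sections`` maps foreign section tags to concept categories,
    ``items`` maps foreign definition tags to the dialect's item tags,
    and ``fields`` maps foreign attribute names to the dialect's.
    The identity profile accepts the dialect itself.
    """

    sections: Mapping[str, str] = field(default_factory=dict)
    items: Mapping[str, str] = field(default_factory=dict)
    fields: Mapping[str, str] = field(default_factory=dict)

    def section_category(self, tag: str) -> str:
        tag = self.sections.get(tag, tag)
        for category, canonical in _SECTION_TAG.items():
            if tag == canonical:
                return category
        raise SchemaError(f"unmappable category section tag {tag!r}")

    def item_tag(self, tag: str) -> str:
        return self.items.get(tag, tag)

    def field_name(self, name: str) -> str:
        return self.fields.get(name, name)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "TagProfile":
        return cls(
            sections=dict(data.get("sections", {})),
            items=dict(data.get("items", {})),
            fields=dict(data.get("fields", {})),
        )


IDENTITY_PROFILE = TagProfile()


def _read_attrdef(node, profile: TagProfile) -> AttributeDef:
    attrs = {profile.field_name(k): v for k, v in node.attrib.items()}
    allowed = [
        a.get(profile.field_name("value"), a.get("value"))
        for a in node
        if profile.item_tag(a.tag) == "allowed"
    ]
    return AttributeDef(
        name=attrs["name"],
        kind=attrs.get("kind", "text"),
        required=_parse_bool(attrs.get("required"), False),
        allowed_values=tuple(allowed) or None,
    )


def _read_form(node, profile: TagProfile) -> AnnotationFormDef:
    attrs = {profile.field_name(k): v for k, v in node.attrib.items()}
    applicable, attributes, subforms = [], [], []
    for child in node:
        tag = profile.item_tag(child.tag)
        if tag == "applies-to":
            cattrs = {profile.field_name(k): v for k, v in child.attrib.items()}
            applicable.append(cattrs["type"])
        elif tag == "attribute":
            attributes.append(_read_attrdef(child, profile))
        elif tag in ("subform", "annotation-form"):
            subforms.append(_read_form(child, profile))
        else:
            raise SchemaError(f"unexpected tag {child.tag!r} inside annotation form")
    return AnnotationFormDef(
        name=attrs["name"],
        attributes=tuple(attributes),
        subforms=tuple(subforms),
        applicable_to=frozenset(applicable),
    )


def read_model_xml(
    document: bytes | str, profile: TagProfile | None = None
) -> DataModel:
    """Parse a data-model document, optionally through a tag profile.

    Raises :class:`SchemaError` naming the offending tag when a section
    cannot be mapped to one of the seven categories, and raises with the
    full violation list when the parsed model breaks an invariant.
    """
    profile = profile or IDENTITY_PROFILE
    if isinstance(document, str):
        document = document.encode("utf-8")
    root = etree.fromstring(document)
    model = DataModel()
    for section in root:
        if isinstance(section, etree._Comment):
            continue
        category = profile.section_category(section.tag)
        defs = dict(model.category(category))
        for node in section:
            if isinstance(node, etree._Comment):
                continue
            tag = profile.item_tag(node.tag)
            if tag != _ITEM_TAG[category]:
                raise SchemaError(
                    f"unexpected tag {node.tag!r} in {category} section"
                )
            attrs = {profile.field_name(k): v for k, v in node.attrib.items()}
            if category == "element":
                d = ElementTypeDef(attrs["name"], attrs.get("description", ""))
            elif category == "relation":
                sources, targets = [], []
                for child in node:
                    ctag = profile.item_tag(child.tag)
                    cattrs = {
                        profile.field_name(k): v for k, v in child.attrib.items()
                    }
                    if ctag == "source":
                        sources.append(cattrs["type"])
                    elif ctag == "target":
                        targets.append(cattrs["type"])
                    else:
                        raise SchemaError(
                            f"unexpected tag {child.tag!r} inside relation type"
                        )
                d = RelationTypeDef(
                    attrs["name"],
                    frozenset(sources),
                    frozenset(targets),
                    directed=_parse_bool(attrs.get("directed"), True),
                    description=attrs.get("description", ""),
                )
            elif category == "annotation_form":
                d = _read_form(node, profile)
            elif category == "experiment_format":
                columns = [
                    _read_attrdef(c, profile)
                    for c in node
                    if profile.item_tag(c.tag) == "column"
                ]
                d = ExperimentFormatDef(
                    attrs["name"], attrs.get("entity-type", ""), tuple(columns)
                )
            elif category == "context":
                d = ContextTypeDef(attrs["name"], attrs.get("description", ""))
            elif category == "ontology":
                d = OntologyDef(attrs["name"], attrs.get("source-format", "obo"))
            else:
                columns = [
                    _read_attrdef(c, profile)
                    for c in node
                    if profile.item_tag(c.tag) == "attribute"
                ]
                d = ExternalSourceDef(
                    attrs["name"], attrs.get("adapter-id", ""), tuple(columns)
                )
            if d.name in defs:
                raise SchemaError(f"duplicate {category} name {d.name!r} in document")
            defs[d.name] = d
        model = replace(model, **{_CATEGORY_FIELD[category]: defs})
    violations = validate_model(model)
    if violations:
        raise SchemaError(
            "document parses but the model is invalid: "
            + "; ".join(str(v) for v in violations)
        )
    return model
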