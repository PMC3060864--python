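"""Data-model definitions, validation, and XML (de)serialisation."""

import itertools

import pytest

from semkb.fixtures import SCALED_EXPORT_PROFILE, synthetic_scaled_model_export
from semkb.schema import (
    AnnotationFormDef,
    AttributeDef,
    ContextTypeDef,
    DataModel,
    ElementTypeDef,
    ExperimentFormatDef,
    OntologyDef,
    RelationTypeDef,
    SchemaError,
    TagProfile,
    count_definitions,
    define_type,
    read_model_xml,
    validate_model,
    write_model_xml,
)


def test_define_element_type_on_empty_model():
    model = define_type(DataModel(), "element", ElementTypeDef("Gene"))
    assert count_definitions(model, "element") == 1
    assert model.element_type("Gene").name == "Gene"


def test_define_relation_stores_endpoint_constraint():
    model = DataModel()
    for name in ("Patient", "Compound"):
        model = define_type(model, "element", ElementTypeDef(name))
    model = define_type(
        model,
        "relation",
        RelationTypeDef("is medicated by", {"Patient"}, {"Compound"}),
    )
    rtd = model.relation_type("is medicated by")
    assert rtd.source_types == {"Patient"} and rtd.target_types == {"Compound"}


def test_dangling_endpoint_reference_rejected_naming_the_type():
    model = define_type(DataModel(), "element", ElementTypeDef("Gene"))
    with pytest.raises(SchemaError, match="Plasmid"):
        define_type(
            model, "relation", RelationTypeDef("carries", {"Gene"}, {"Plasmid"})
        )


def test_duplicate_name_rejected_and_model_unchanged():
    model = define_type(DataModel(), "element", ElementTypeDef("Gene"))
    with pytest.raises(SchemaError, match="duplicate"):
        define_type(model, "element", ElementTypeDef("Gene"))
    assert count_definitions(model, "element") == 1


def test_failed_definition_is_not_partially_applied():
    model = DataModel()
    with pytest.raises(SchemaError):
        define_type(model, "relation", RelationTypeDef("r", {"X"}, {"Y"}))
    assert validate_model(model) == []
    assert count_definitions(model, "relation") == 0


def test_validate_model_reports_violations_as_data():
    # hand-assembled invalid model (bypassing define_type)
    model = DataModel(
        element_types={"Gene": ElementTypeDef("Gene")},
        relation_types={
            "binds": RelationTypeDef("binds", {"Gene"}, {"Nonexistent"})
        },
        experiment_formats={
            "assay": ExperimentFormatDef("assay", "Missing", (AttributeDef("v"),))
        },
    )
    violations = validate_model(model)
    rules = {(v.category, v.name) for v in violations}
    assert ("relation", "binds") in rules
    assert ("experiment_format", "assay") in rules


def test_validate_empty_model_is_clean():
    assert validate_model(DataModel()) == []


def test_allowed_values_only_for_controlled_terms():
    with pytest.raises(SchemaError, match="allowed_values"):
        AttributeDef("Age", "integer", allowed_values=("a",))


@pytest.mark.parametrize("category,definition", [
    ("element", ElementTypeDef("Gene", "a gene")),
    ("context", ContextTypeDef("pathway")),
    ("ontology", OntologyDef("GO-like", "obo")),
])
def test_xml_round_trip_single_definition(category, definition):
    model = define_type(DataModel(), category, definition)
    assert read_model_xml(write_model_xml(model)) == model


def test_xml_round_trip_full_fixture_model(model):
    document = write_model_xml(model)
    assert read_model_xml(document) == model
    # serialisation is deterministic
    assert write_model_xml(read_model_xml(document)) == document


def test_empty_model_serialises_with_empty_sections():
    document = write_model_xml(DataModel())
    assert read_model_xml(document) == DataModel()


def test_define_type_order_insensitive():
    defs = [
        ("element", ElementTypeDef("Gene")),
        ("element", ElementTypeDef("Protein")),
        ("context", ContextTypeDef("pathway")),
        ("ontology", OntologyDef("GO-like")),
    ]
    models = []
    for perm in itertools.permutations(defs):
        m = DataModel()
        for category, d in perm:
            m = define_type(m, category, d)
        models.append(m)
    assert all(m == models[0] for m in models)


def test_models_built_through_define_type_always_validate(model):
    assert validate_model(model) == []


def test_unknown_category_tag_rejected_by_name():
    doc = b"<data-model><mystery-section/></data-model>"
    with pytest.raises(SchemaError, match="mystery-section"):
        read_model_xml(doc)


def test_unknown_category_rejected():
    with pytest.raises(SchemaError, match="unknown concept category"):
        count_definitions(DataModel(), "gizmo")


def test_profile_maps_foreign_vocabulary():
    foreign = (
        b"<data-model><objects><object label='Gene'/></objects></data-model>"
    )
    profile = TagProfile(
        sections={"objects": "element-types"},
        items={"object": "element-type"},
        fields={"label": "name"},
    )
    parsed = read_model_xml(foreign, profile)
    assert count_definitions(parsed, "element") == 1
    assert parsed.element_type("Gene")


def test_scaled_export_parses_only_through_its_profile():
    """The synthetic full-scale export uses a foreign vocabulary end to end."""
    document = synthetic_scaled_model_export(
        n_element_types=3, n_relation_types=4, n_annotation_forms=2,
        n_attributes=10, n_experiment_formats=1, n_context_types=2,
        n_ontologies=2,
    )
    with pytest.raises(SchemaError):
        read_model_xml(document)
    parsed = read_model_xml(document, SCALED_EXPORT_PROFILE)
    assert count_definitions(parsed, "element") == 3
    assert count_definitions(parsed, "relation") == 4
    assert sum(len(f.attributes) for f in parsed.annotation_forms.values()) == 10


def test_nested_form_round_trips(model):
    form = model.annotation_form("interaction evidence")
    assert form.subforms and form.subforms[0].name == "provenance"
    parsed = read_model_xml(write_model_xml(model))
    assert parsed.annotation_form("interaction evidence") == form
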