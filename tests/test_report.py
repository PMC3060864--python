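"""Report rendering, nesting, view items, exports."""

import pytest

from semkb.fixtures import FixtureSpec, generate_kb
from semkb.query import evaluate, bind_variables, parse_query
from semkb.report import (
    ReportDef,
    ReportError,
    Table,
    ViewItem,
    export_report,
    parse_report_xml,
    render_report,
    report_def_from_mapping,
    validate_report,
)


@pytest.fixture()
def kb():
    kb, _ = generate_kb(FixtureSpec(seed=11, n_patients=10, n_genes=8,
                                    n_proteins=8, n_compounds=4,
                                    n_pathways=3, ontology_size=14))
    return kb


def gene_report():
    return ReportDef("gene overview", "Gene", (
        ViewItem("diseases", "related_objects",
                 relation="gene-disease association"),
        ViewItem("compounds", "related_objects",
                 relation="gene-compound interaction"),
        ViewItem("pathways", "context_membership", context_type="pathway"),
        ViewItem("fold change", "experiment_values", format="Expression",
                 column="fold_change"),
    ))


def test_one_row_per_object_in_input_order(kb):
    genes = [g.ref for g in kb.elements_of_type("Gene")]
    table = render_report(kb, gene_report(), genes)
    assert len(table.rows) == len(genes)
    reversed_table = render_report(kb, gene_report(), list(reversed(genes)))
    assert reversed_table.rows == list(reversed(table.rows))


def test_empty_object_list_gives_header_only_table(kb):
    table = render_report(kb, gene_report(), [])
    assert table.headers == ("diseases", "compounds", "pathways", "fold change")
    assert table.rows == []


def test_type_mismatch_rejected(kb):
    patient = kb.elements_of_type("Patient")[0]
    with pytest.raises(ReportError, match="Gene"):
        render_report(kb, gene_report(), [patient.ref])


def test_cyclic_nesting_caught_at_definition_time(kb):
    a = ReportDef("a", "Gene", (
        ViewItem("again", "related_objects", relation="genetic interaction",
                 rendered_by="b"),
    ))
    b = ReportDef("b", "Gene", (
        ViewItem("back", "related_objects", relation="genetic interaction",
                 rendered_by="a"),
    ))
    with pytest.raises(ReportError, match="cyclic"):
        validate_report(a, kb.model, {"a": a, "b": b})


def test_nested_report_equals_standalone_rendering(kb):
    protein_report = ReportDef("protein detail", "Protein", (
        ViewItem("interactions", "related_objects",
                 relation="protein interaction"),
    ))
    outer = ReportDef("gene+protein", "Gene", (
        ViewItem("protein", "related_objects", relation="expressed as",
                 direction="out", rendered_by="protein detail"),
    ))
    registry = {"protein detail": protein_report}
    gene = kb.elements_of_type("Gene")[0]
    table = render_report(kb, outer, [gene.ref], registry)
    nested = table.rows[0][0]
    assert isinstance(nested, Table)
    partners = [
        rel.target if rel.source == gene.ref else rel.source
        for rel in kb.relations_of(gene.ref, ["expressed as"])
    ]
    standalone = render_report(kb, protein_report, sorted(partners))
    assert nested.rows == standalone.rows


def test_query_result_cells_match_direct_evaluation(kb):
    per_row_query = parse_query({
        "find": "Gene",
        "where": {"all": [
            {"is_object": {"var": "row"}},
            {"in_context": {"context_type": "pathway"}},
        ]},
    }, kb.model)
    report = ReportDef("gene pathways", "Gene", (
        ViewItem("in any pathway", "query_result", query=per_row_query,
                 aggregate="count"),
    ))
    genes = [g.ref for g in kb.elements_of_type("Gene")]
    table = render_report(kb, report, genes)
    for ref, row in zip(genes, table.rows):
        direct = evaluate(kb, bind_variables(per_row_query, {"row": ref}))
        assert row[0] == len(direct)


def test_computed_column_registry(kb):
    report = ReportDef("names", "Gene", (
        ViewItem("name", "computed", function="display_name"),
    ))
    genes = [g.ref for g in kb.elements_of_type("Gene")[:3]]
    table = render_report(
        kb, report, genes,
        computed={"display_name": lambda kb_, r: kb_.describe(r)[2]},
    )
    assert table.rows[0][0] == kb.describe(genes[0])[2]
    with pytest.raises(ReportError, match="display_name"):
        render_report(kb, report, genes)


def test_tsv_export_shape(kb):
    genes = [g.ref for g in kb.elements_of_type("Gene")[:3]]
    table = render_report(kb, gene_report(), genes)
    tsv = export_report(table, "tsv")
    lines = tsv.rstrip("\n").split("\n")
    assert len(lines) == 4  # header + 3 data lines
    assert lines[0] == "diseases\tcompounds\tpathways\tfold change"


def test_xml_export_round_trip_is_byte_identical(kb):
    protein_report = ReportDef("protein detail", "Protein", (
        ViewItem("interactions", "related_objects",
                 relation="protein interaction"),
    ))
    outer = ReportDef("gene+protein", "Gene", (
        ViewItem("protein", "related_objects", relation="expressed as",
                 rendered_by="protein detail"),
        ViewItem("fold change", "experiment_values", format="Expression",
                 column="fold_change"),
    ))
    genes = [g.ref for g in kb.elements_of_type("Gene")[:4]]
    table = render_report(kb, outer, genes, {"protein detail": protein_report})
    xml = export_report(table, "xml")
    assert export_report(parse_report_xml(xml), "xml") == xml


def test_unknown_export_format_rejected(kb):
    table = render_report(kb, gene_report(), [])
    with pytest.raises(ReportError, match="pdf"):
        export_report(table, "pdf")


def test_report_def_from_mapping_validates(kb):
    mapping = {
        "name": "patient overview",
        "object_type": "Patient",
        "items": [
            {"label": "age", "source": "own_attribute",
             "form": "Patient Anthropometrics", "attribute": "Age"},
            {"label": "medication", "source": "related_objects",
             "relation": "is medicated by", "direction": "out"},
        ],
    }
    report = report_def_from_mapping(mapping, kb.model)
    patients = [p.ref for p in kb.elements_of_type("Patient")[:2]]
    table = render_report(kb, report, patients)
    assert table.headers == ("age", "medication")
    assert isinstance(table.rows[0][0], int)
    with pytest.raises(Exception, match="Vitals"):
        report_def_from_mapping(
            {"object_type": "Patient", "items": [
                {"label": "x", "source": "assigned_annotation", "form": "Vitals"}
            ]},
            kb.model,
        )
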