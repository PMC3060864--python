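"""Import templates: compilation, entity resolution, row atomicity."""

import pytest

from semkb.importer import (
    ImportError_,
    TsvAdapter,
    compile_template,
    read_table,
    resolve_entity,
    run_import,
)
from semkb.store import KnowledgeBase, StoreError

PPI_TEMPLATE = """
name: ppi-import
columns: [uniprot_a, uniprot_b, method]
operations:
  - op: make_element
    handle: p1
    type: Protein
    identifier: {namespace: UniProt, column: uniprot_a}
  - op: make_element
    handle: p2
    type: Protein
    identifier: {namespace: UniProt, column: uniprot_b}
  - op: make_relation
    handle: r1
    type: protein interaction
    source: p1
    target: p2
  - op: attach_annotation
    form: interaction evidence
    to: [r1]
    values: {Method: {column: method}}
"""


@pytest.fixture()
def kb(model):
    return KnowledgeBase(model)


def ppi_rows(n=10):
    return [
        {"uniprot_a": f"A{i:03d}", "uniprot_b": f"B{i:03d}", "method": "Y2H"}
        for i in range(n)
    ]


def test_protein_interaction_template_compiles(model):
    template = compile_template(model, PPI_TEMPLATE)
    assert [op.op_kind for op in template.operations] == [
        "make_element", "make_element", "make_relation", "attach_annotation",
    ]
    assert template.handle_types["p1"] == "Protein"


def test_relation_not_applicable_to_upstream_types_rejected(model):
    bad = PPI_TEMPLATE.replace("type: protein interaction", "type: is medicated by")
    with pytest.raises(ImportError_, match="is medicated by"):
        compile_template(model, bad)


def test_empty_operation_list_compiles_to_noop(model, kb):
    template = compile_template(model, {"name": "noop", "columns": [], "operations": []})
    report = run_import(kb, template, [{"x": 1}])
    assert report.accepted == 1 and report.created == {}


def test_undeclared_column_rejected(model):
    bad = PPI_TEMPLATE.replace("column: method", "column: evidence_code")
    with pytest.raises(ImportError_, match="evidence_code"):
        compile_template(model, bad)


def test_resolve_entity_identifier_contract(kb):
    ref1, created1 = resolve_entity(kb, "Protein", "UniProt", "P04049")
    assert created1 is True
    ref2, created2 = resolve_entity(kb, "Protein", "UniProt", "P04049")
    assert created2 is False and ref2 == ref1
    # the same identifier on a different type is a conflict, never reuse
    with pytest.raises(StoreError, match="P04049"):
        resolve_entity(kb, "Gene", "UniProt", "P04049")


def test_import_creates_elements_and_relations(model, kb):
    template = compile_template(model, PPI_TEMPLATE)
    report = run_import(kb, template, ppi_rows())
    assert report.rows_processed == 10 and report.accepted == 10
    assert report.created["element"] == 20
    assert report.created["relation"] == 10
    assert report.created["annotation"] == 10
    assert report.skipped == []


def test_second_run_is_idempotent(model, kb):
    template = compile_template(model, PPI_TEMPLATE)
    run_import(kb, template, ppi_rows())
    audit_before = len(kb.audit)
    state_before = (dict(kb.elements), dict(kb.relations), dict(kb.annotations))
    report = run_import(kb, template, ppi_rows())
    assert report.created == {}
    assert report.mapped_to_existing == 20
    assert len(kb.audit) == audit_before
    assert (dict(kb.elements), dict(kb.relations), dict(kb.annotations)) == state_before


def test_reference_target_type_constraint_skips_row_atomically(model, kb):
    # a transcript catalogue where one reference points at a Protein entry
    # instead of the required mRNA entry type
    kb.create_element("mRNA", "NM_0001", [("RefSeq", "NM_0001")])
    kb.create_element("Protein", "stray", [("RefSeq", "XP_9999")])
    template = compile_template(model, """
name: gene-from-transcript
columns: [gene_acc, transcript_ref]
operations:
  - op: make_element
    handle: g
    type: Gene
    identifier: {namespace: EntrezGene, column: gene_acc}
  - op: map_by_reference
    handle: t
    reference: {namespace: RefSeq, column: transcript_ref}
    require_type: mRNA
  - op: make_relation
    type: transcribed as
    source: g
    target: t
""")
    audit_before = len(kb.audit)
    report = run_import(kb, template, [
        {"gene_acc": "111", "transcript_ref": "NM_0001"},
        {"gene_acc": "222", "transcript_ref": "XP_9999"},
        {"gene_acc": "333", "transcript_ref": "NM_MISSING"},
    ])
    assert report.accepted == 1
    assert [n for n, _ in report.skipped] == [2, 3]
    assert "mRNA" in report.skipped[0][1]
    # skipped rows contributed nothing: only row 1's two mutations logged
    new_records = kb.audit[audit_before:]
    assert len(new_records) == 2
    assert not any(
        e.name == "222" or e.name == "333" for e in kb.elements.values()
    )


def test_missing_declared_column_rejected_before_processing(model, kb):
    template = compile_template(model, PPI_TEMPLATE)
    with pytest.raises(ImportError_, match="uniprot_b"):
        run_import(kb, template, [{"uniprot_a": "A", "method": "x"}])
    assert len(kb.audit) == 0


def test_malformed_numeric_value_skips_row(model, kb):
    template = compile_template(model, """
name: expression
columns: [gene_acc, fc]
operations:
  - op: make_element
    handle: g
    type: Gene
    identifier: {namespace: EntrezGene, column: gene_acc}
  - op: add_experiment_row
    format: Expression
    label: trial
    element: g
    values: {fold_change: {column: fc}}
""")
    report = run_import(kb, template, [
        {"gene_acc": "1", "fc": "1.5"},
        {"gene_acc": "2", "fc": "not-a-number"},
    ])
    assert report.accepted == 1
    assert len(report.skipped) == 1 and "fold_change" in report.skipped[0][1]
    tables = [t for t in kb.experiments.values() if t.label == "trial"]
    assert len(tables) == 1 and len(tables[0].rows) == 1


def test_context_accumulates_members_across_rows_idempotently(model, kb):
    template = compile_template(model, """
name: pathway-members
columns: [gene_acc, pathway]
operations:
  - op: make_element
    handle: g
    type: Gene
    identifier: {namespace: EntrezGene, column: gene_acc}
  - op: add_to_context
    context_type: pathway
    name_from: pathway
    member: g
""")
    rows = [
        {"gene_acc": "1", "pathway": "glycolysis-like"},
        {"gene_acc": "2", "pathway": "glycolysis-like"},
        {"gene_acc": "3", "pathway": "signalling-like"},
    ]
    run_import(kb, template, rows)
    contexts = {c.name: c for c in kb.contexts.values()}
    assert len(contexts["glycolysis-like"].members) == 2
    audit_before = len(kb.audit)
    run_import(kb, template, rows)
    assert len(kb.audit) == audit_before


def test_read_table_parses_delimited_text():
    rows = read_table("a\tb\n1\t2\n3\t4\n")
    assert rows == [{"a": "1", "b": "2"}, {"a": "3", "b": "4"}]


def test_tsv_adapter_contract():
    adapter = TsvAdapter(
        "accession\tvariant\tgene\nrs1\tA>G\tMAPK14\nrs2\tC>T\tTNF\n",
        namespace="dbSNP-like",
    )
    assert adapter.attributes() == ["accession", "variant", "gene"]
    assert adapter.lookup("rs1")["variant"] == "A>G"
    assert adapter.lookup("rs404") is None
    assert [r["accession"] for r in adapter.search("gene", "MAPK*")] == ["rs1"]
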