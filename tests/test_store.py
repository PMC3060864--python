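"""Instance store: validation, audit trail, replay, persistence."""

import pytest

from semkb.fixtures import (
    DISEASE_ONTOLOGY,
    FixtureSpec,
    build_disease_ontology,
    build_model,
    generate_kb,
)
from semkb.store import KnowledgeBase, StoreError, replay_audit


@pytest.fixture()
def kb(model):
    return KnowledgeBase(model)


def test_create_element_and_resolve_identifier(kb):
    ref = kb.create_element("Gene", "MAPK14", [("EntrezGene", "1432")])
    assert ref.kind == "element"
    assert kb.resolve_identifier("EntrezGene", "1432") == ref
    assert kb.get(ref).name == "MAPK14"


def test_undeclared_element_type_rejected(kb):
    with pytest.raises(Exception, match="Plasmid"):
        kb.create_element("Plasmid", "x", [])


def test_identifier_collision_names_existing_owner(kb):
    kb.create_element("Protein", "RAF1", [("UniProt", "P04049")])
    with pytest.raises(StoreError, match="RAF1"):
        kb.create_element("Protein", "other", [("UniProt", "P04049")])


def test_every_creation_appends_one_audit_record(kb):
    for i in range(50):
        kb.create_element("Gene", f"G{i}", [("EntrezGene", str(i))])
    creates = [r for r in kb.audit if r.action == "create"]
    assert len(creates) == 50
    assert [r.seq for r in kb.audit] == list(range(1, len(kb.audit) + 1))


def test_failed_operation_appends_no_audit_record(kb):
    kb.create_element("Gene", "G1", [("EntrezGene", "1")])
    before = len(kb.audit)
    with pytest.raises(StoreError):
        kb.create_element("Gene", "G2", [("EntrezGene", "1")])
    assert len(kb.audit) == before


def test_relation_constraint_enforced(kb):
    gene = kb.create_element("Gene", "G", [])
    compound = kb.create_element("Compound", "C", [])
    with pytest.raises(StoreError, match="is medicated by"):
        kb.create_relation("is medicated by", gene, compound)


def test_duplicate_relation_triple_rejected(kb):
    a = kb.create_element("Protein", "A", [])
    b = kb.create_element("Protein", "B", [])
    kb.create_relation("protein interaction", a, b)
    before = len(kb.audit)
    with pytest.raises(StoreError, match="duplicate"):
        kb.create_relation("protein interaction", a, b)
    # undirected: the reversed triple is the same edge
    with pytest.raises(StoreError, match="duplicate"):
        kb.create_relation("protein interaction", b, a)
    assert len(kb.audit) == before


def test_annotation_requires_targets_and_applicability(kb):
    patient = kb.create_element("Patient", "P1", [])
    values = {"Age": 54, "Sex": "male", "BMI-BeforeTraining": 24.2}
    ref = kb.attach_annotation("Patient Anthropometrics", values, [patient])
    assert kb.get(ref).values["Age"] == 54
    with pytest.raises(StoreError, match="at least one target"):
        kb.attach_annotation("Patient Anthropometrics", values, [])
    gene = kb.create_element("Gene", "G", [])
    with pytest.raises(StoreError, match="not applicable"):
        kb.attach_annotation("Patient Anthropometrics", values, [gene])


def test_annotation_on_relation_allowed(kb):
    a = kb.create_element("Protein", "A", [])
    b = kb.create_element("Protein", "B", [])
    rel = kb.create_relation("protein interaction", a, b)
    ref = kb.attach_annotation(
        "interaction evidence",
        {"Method": "Y2H", "provenance": {"database": "reactome-like"}},
        [rel],
    )
    assert rel in kb.get(ref).attached_to


def test_required_attribute_enforced(kb):
    patient = kb.create_element("Patient", "P1", [])
    with pytest.raises(StoreError, match="Age"):
        kb.attach_annotation("Patient Anthropometrics", {"Sex": "male"}, [patient])


def test_controlled_term_vocabulary_enforced(kb):
    patient = kb.create_element("Patient", "P1", [])
    with pytest.raises(StoreError, match="allowed values"):
        kb.attach_annotation(
            "Patient Anthropometrics", {"Age": 50, "Sex": "unknown"}, [patient]
        )


def test_shared_annotation_attaches_to_many_objects(kb):
    p1 = kb.create_element("Patient", "P1", [])
    p2 = kb.create_element("Patient", "P2", [])
    ref = kb.attach_annotation(
        "Patient diagnostic data", {"GOLD": 2}, [p1, p2]
    )
    assert {a.ref for a in kb.annotations_of(p1)} == {ref}
    assert {a.ref for a in kb.annotations_of(p2)} == {ref}


def test_experiment_rows_validated_and_retrievable(kb):
    genes = [kb.create_element("Gene", f"G{i}", []) for i in range(5)]
    rows = [(g, {"fold_change": 0.5 * i}) for i, g in enumerate(genes)]
    kb.record_experiment("Expression", "trial", rows)
    hits = kb.experiment_rows_of(genes[2], "Expression", "trial")
    assert len(hits) == 1 and hits[0][1]["fold_change"] == 1.0
    # empty table is valid
    kb.record_experiment("Expression", "empty", [])
    patient = kb.create_element("Patient", "P", [])
    with pytest.raises(StoreError, match="Gene"):
        kb.record_experiment("Expression", "bad", [(patient, {"fold_change": 1.0})])


def test_context_membership_queryable_both_ways(kb):
    genes = [kb.create_element("Gene", f"G{i}", []) for i in range(12)]
    ctx = kb.build_context("pathway", "glycolysis-like", genes)
    assert kb.get(ctx).members == frozenset(genes)
    for g in genes:
        assert ctx in {c.ref for c in kb.contexts_of(g)}
    empty = kb.build_context("pathway", "empty", [])
    assert kb.get(empty).members == frozenset()


def test_neighborhood_filters_by_relation_type(kb):
    kb.attach_ontology(build_disease_ontology(20))
    gene = kb.create_element("Gene", "MAPK14", [])
    compound = kb.create_element("Compound", "C1", [])
    term = kb.term_ref(DISEASE_ONTOLOGY, "D:0000010")
    kb.create_relation("gene-compound interaction", gene, compound)
    kb.create_relation("gene-disease association", gene, term)
    full = kb.neighborhood(gene)
    assert full.nodes == {gene, compound, term}
    diseases_only = kb.neighborhood(gene, {"gene-disease association"})
    assert diseases_only.nodes == {gene, term}
    isolated = kb.create_element("Gene", "alone", [])
    assert kb.neighborhood(isolated).nodes == {isolated}
    assert kb.neighborhood(isolated).edges == frozenset()


def test_delete_refuses_then_cascades_with_force(kb):
    a = kb.create_element("Protein", "A", [])
    b = kb.create_element("Protein", "B", [])
    rel = kb.create_relation("protein interaction", a, b)
    with pytest.raises(StoreError, match="referenced by"):
        kb.delete(a)
    kb.delete(a, force=True)
    assert not kb.exists(a) and not kb.exists(rel) and kb.exists(b)
    assert kb.check_integrity() == []


def test_replay_audit_reconstructs_fixture_kb():
    kb, _ = generate_kb(FixtureSpec(seed=3, n_patients=10, n_genes=5,
                                    n_proteins=5, n_compounds=3,
                                    n_pathways=2, ontology_size=14))
    rebuilt = replay_audit(kb.model, kb.audit)
    assert rebuilt == kb


def test_replay_empty_log_gives_empty_kb(model):
    kb = replay_audit(model, [])
    assert not kb.elements and not kb.audit


def test_replay_rejects_sequence_gap(kb):
    kb.create_element("Gene", "G1", [])
    kb.create_element("Gene", "G2", [])
    import dataclasses

    broken = [kb.audit[0], dataclasses.replace(kb.audit[1], seq=5)]
    with pytest.raises(StoreError, match="out of order"):
        replay_audit(kb.model, broken)


def test_dump_load_round_trip(tmp_path):
    kb, _ = generate_kb(FixtureSpec(seed=5, n_patients=8, n_genes=4,
                                    n_proteins=4, n_compounds=2,
                                    n_pathways=1, ontology_size=14))
    kb.dump(tmp_path / "kb")
    loaded = KnowledgeBase.load(tmp_path / "kb")
    assert loaded == kb
    assert loaded.check_integrity() == []


def test_referential_integrity_after_mixed_operations(kb):
    kb.attach_ontology(build_disease_ontology(14))
    patients = [kb.create_element("Patient", f"P{i}", []) for i in range(5)]
    compound = kb.create_element("Compound", "C", [])
    for p in patients:
        kb.create_relation("is medicated by", p, compound)
        kb.attach_annotation("Patient diagnostic data", {"GOLD": 1}, [p])
    kb.build_context("disease process", "proc", patients[:2])
    kb.delete(patients[0], force=True)
    assert kb.check_integrity() == []


def test_extend_context_logged_and_replayable(kb):
    genes = [kb.create_element("Gene", f"G{i}", []) for i in range(4)]
    ctx = kb.build_context("pathway", "p", genes[:2])
    kb.extend_context(ctx, genes[2:])
    assert kb.get(ctx).members == frozenset(genes)
    assert replay_audit(kb.model, kb.audit) == kb
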