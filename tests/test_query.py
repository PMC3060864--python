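"""Query parsing, variable binding, evaluation, oracle equivalence."""

import random

import pytest

from conftest import random_query, small_spec
from semkb.fixtures import (
    DISEASE_ONTOLOGY,
    FixtureSpec,
    benchmark_queries,
    generate_kb,
)
from semkb.query import (
    And,
    AnnotatedBy,
    Not,
    OntologyLinked,
    Query,
    QueryError,
    SmartFolder,
    bind_variables,
    brute_force_evaluate,
    evaluate,
    evaluate_smart_folder,
    parse_query,
)


def test_patient_training_query_parses_to_conjunction_of_three_forms(model):
    query = benchmark_queries()["fig3-patient-training"]
    assert isinstance(query.root, And) and len(query.root.clauses) == 3
    assert all(isinstance(c, AnnotatedBy) for c in query.root.clauses)
    assert sum(len(c.comparisons) for c in query.root.clauses) == 7


def test_never_diagnosed_query_parses_with_negated_inference(model):
    query = benchmark_queries()["severe-low-bmi-no-cancer"]
    negations = [c for c in query.root.clauses if isinstance(c, Not)]
    assert len(negations) == 1
    assert isinstance(negations[0].clause, OntologyLinked)
    assert negations[0].clause.name_like == "*cancer*"


def test_unknown_form_rejected_by_name(model):
    bad = {"find": "Patient",
           "where": {"annotated_by": {"form": "Vitals", "has": []}}}
    with pytest.raises(Exception, match="Vitals"):
        parse_query(bad, model)


def test_like_on_numeric_attribute_rejected(model):
    bad = {"find": "Patient", "where": {"annotated_by": {
        "form": "Patient diagnostic data",
        "has": [{"attribute": "GOLD", "op": "like", "value": "2"}],
    }}}
    with pytest.raises(QueryError, match="like"):
        parse_query(bad, model)


def test_bind_variables_substitutes_literals():
    query = benchmark_queries()["severe-low-bmi-no-cancer"]
    bound = bind_variables(query, {"gold_min": 3})
    gold = bound.root.clauses[0].comparisons[0]
    assert gold.value == 3
    bmi = bound.root.clauses[1].comparisons[0]
    assert bmi.value == 18  # default filled in


def test_bind_without_variables_is_identity():
    query = benchmark_queries()["fig3-patient-training"]
    assert bind_variables(query, {}).root == query.root


def test_missing_required_binding_names_the_variable(model):
    source = {
        "find": "Patient",
        "where": {"annotated_by": {
            "form": "Patient diagnostic data",
            "has": [{"attribute": "GOLD", "op": "gt", "value": {"var": "cutoff"}}],
        }},
        "variables": {"cutoff": {"kind": "integer"}},
    }
    query = parse_query(source, model)
    with pytest.raises(QueryError, match="cutoff"):
        bind_variables(query, {})


def test_unbound_query_cannot_be_evaluated(small_kb):
    kb, _ = small_kb
    query = benchmark_queries()["severe-low-bmi-no-cancer"]
    with pytest.raises(QueryError, match="not fully bound"):
        evaluate(kb, query)


def test_contradictory_comparisons_give_empty_result(small_kb):
    kb, _ = small_kb
    query = parse_query({
        "find": "Patient",
        "where": {"annotated_by": {
            "form": "Patient Anthropometrics",
            "has": [
                {"attribute": "Age", "op": "gt", "value": 30},
                {"attribute": "Age", "op": "lt", "value": 20},
            ],
        }},
    }, kb.model)
    assert evaluate(kb, query) == []


def test_fixture_benchmark_queries_match_recorded_ground_truth(small_kb):
    kb, truth = small_kb
    for name, query in benchmark_queries().items():
        bound = bind_variables(query, {}) if query.variables else query
        assert tuple(r.id for r in evaluate(kb, bound)) == \
            truth.satisfying_patients[name]


@pytest.mark.parametrize("trial", range(25))
def test_evaluate_equals_brute_force_on_random_kb_query_pairs(trial):
    rng = random.Random(4000 + trial)
    kb, _ = generate_kb(small_spec(seed=5000 + trial))
    for _ in range(4):
        query = random_query(rng, kb.model, depth=rng.randint(1, 4))
        assert evaluate(kb, query) == brute_force_evaluate(kb, query)


def test_not_is_complement_within_target_type(small_kb):
    kb, _ = small_kb
    rng = random.Random(99)
    for _ in range(5):
        query = random_query(rng, kb.model, depth=2)
        inside = set(evaluate(kb, query))
        outside = set(evaluate(kb, Query(query.target_type, Not(query.root))))
        everyone = {e.ref for e in kb.elements_of_type(query.target_type)}
        assert inside | outside == everyone
        assert inside & outside == set()


def test_and_or_monotonicity(small_kb):
    kb, _ = small_kb
    rng = random.Random(123)
    from semkb.query import Or

    for _ in range(5):
        a = random_query(rng, kb.model, depth=2)
        b = random_query(rng, kb.model, depth=2)
        if b.target_type != a.target_type:
            continue
        conj = set(evaluate(kb, Query(a.target_type, And((a.root, b.root)))))
        disj = set(evaluate(kb, Query(a.target_type, Or((a.root, b.root)))))
        base = set(evaluate(kb, a))
        assert conj <= base <= disj


def test_inference_from_root_term_covers_descendant_terms(small_kb):
    kb, _ = small_kb
    root_q = Query("Patient", OntologyLinked(
        "is diagnosed with", name_like=None, term_id="D:0000002",
        ontology=DISEASE_ONTOLOGY))
    child_q = Query("Patient", OntologyLinked(
        "is diagnosed with", name_like=None, term_id="D:0000006",
        ontology=DISEASE_ONTOLOGY))
    assert set(evaluate(kb, root_q)) >= set(evaluate(kb, child_q))


def test_smart_folder_updates_with_kb_changes(small_kb):
    kb, _ = small_kb
    folder = SmartFolder(
        "severe copd", benchmark_queries()["severe-low-bmi-no-cancer"], {}
    )
    before = evaluate_smart_folder(kb, folder)
    new_patient = kb.create_element("Patient", "constructed", [])
    kb.attach_annotation(
        "Patient Anthropometrics",
        {"Age": 60, "Sex": "male", "BMI-BT": 16.0}, [new_patient],
    )
    kb.attach_annotation("Patient diagnostic data", {"GOLD": 4}, [new_patient])
    after = evaluate_smart_folder(kb, folder)
    assert set(after) - set(before) == {new_patient}


def test_smart_folder_override_equals_direct_bound_evaluation(small_kb):
    kb, _ = small_kb
    query = benchmark_queries()["severe-low-bmi-no-cancer"]
    folder = SmartFolder("f", query, {"gold_min": 1})
    assert evaluate_smart_folder(kb, folder, {"gold_min": 3}) == \
        evaluate(kb, bind_variables(query, {"gold_min": 3}))


def test_missing_attribute_fails_comparison_and_negation_includes_it(model):
    from semkb.store import KnowledgeBase

    kb = KnowledgeBase(model)
    recorded = kb.create_element("Patient", "with-age", [])
    kb.attach_annotation(
        "Patient Anthropometrics", {"Age": 45, "Sex": "male"}, [recorded]
    )
    unrecorded = kb.create_element("Patient", "no-anthropometrics", [])
    age_query = parse_query({
        "find": "Patient",
        "where": {"annotated_by": {
            "form": "Patient Anthropometrics",
            "has": [{"attribute": "Age", "op": "gt", "value": 30}],
        }},
    }, model)
    assert evaluate(kb, age_query) == [recorded]
    negated = Query("Patient", Not(age_query.root))
    assert evaluate(kb, negated) == [unrecorded]


def test_brute_force_on_empty_kb(model):
    from semkb.store import KnowledgeBase

    kb = KnowledgeBase(model)
    query = benchmark_queries()["fig3-patient-training"]
    assert brute_force_evaluate(kb, query) == []
    assert evaluate(kb, query) == []
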