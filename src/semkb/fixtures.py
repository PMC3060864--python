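"""Deterministic synthetic COPD-like knowledge base with ground truth.

Everything here emulates, at desk scale, the content of a chronic
obstructive pulmonary disease (COPD) knowledge base: patients carrying
anthropometric, diagnostic and physiology annotation forms; genes,
proteins and compounds linked by interaction, gene–disease and
gene–compound relations; pathway and disease-process contexts; one
expression experiment with fold changes; a small disease thesaurus with
a cancer branch and a small biological-process ontology with a signal
transduction branch.

:func:`generate_kb` is seeded and reproducible; at generation time the
ground truth (which patients satisfy each benchmark query, and the
pairwise seed connection costs) is computed with the *independent*
oracles — the brute-force query evaluator and a library shortest-path
routine — never with the production code paths they are used to check.

Attribute distributions are arbitrary but fixed, chosen so that each
benchmark query selects a nonempty strict subset (roughly 5–30 %) of
patients, exercising both the satisfaction and the rejection branch of
every predicate.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
import networkx as nx

from semkb.network import SearchConfig
from semkb.ontology import OntologyGraph, OntologyTerm
from semkb.query import Query, bind_variables, brute_force_evaluate, parse_query
from semkb.schema import (
    AnnotationFormDef,
    AttributeDef,
    ContextTypeDef,
    DataModel,
    ElementTypeDef,
    ExperimentFormatDef,
    ExternalSourceDef,
    OntologyDef,
    RelationTypeDef,
    TagProfile,
    define_type,
    write_model_xml,
)
from semkb.store import KnowledgeBase, ObjectRef

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "build_model",
    "build_disease_ontology",
    "build_process_ontology",
    "generate_kb",
    "benchmark_queries",
    "fixture_search_config",
    "random_query_mapping",
    "random_query",
    "random_dag_terms",
    "synthetic_scaled_model_export",
    "SCALED_EXPORT_PROFILE",
]

DISEASE_ONTOLOGY = "NCI-like disease thesaurus"
PROCESS_ONTOLOGY = "GO-like process ontology"
EXPRESSION_LABEL = "COPD expression experiment set"


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic knowledge base (all counts >= 0)."""

    seed: int = 42
    n_patients: int = 500
    n_genes: int = 40
    n_proteins: int = 40
    n_compounds: int = 15
    n_pathways: int = 8
    interaction_density: float = 0.08
    ontology_size: int = 60

    def __post_init__(self) -> None:
        for f in (
            "n_patients", "n_genes", "n_proteins", "n_compounds",
            "n_pathways", "ontology_size",
        ):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass
class GroundTruth:
    """Oracle-computed answers recorded while generating the fixture."""

    satisfying_patients: dict = field(default_factory=dict)  # query name -> id tuple
    seed_ids: tuple = ()
    pairwise_path_costs: dict = field(default_factory=dict)  # (id, id) -> cost

    def to_json(self) -> str:
        return json.dumps(
            {
                "satisfying_patients": {
                    k: list(v) for k, v in self.satisfying_patients.items()
                },
                "seed_ids": list(self.seed_ids),
                "pairwise_path_costs": [
                    [a, b, cost] for (a, b), cost in sorted(self.pairwise_path_costs.items())
                ],
            },
            indent=2,
            sort_keys=True,
        )


def build_model() -> DataModel:
    """The reduced COPD-like data model every fixture KB validates against."""
    model = DataModel()
    for name, desc in (
        ("Patient", "study participant"),
        ("Gene", "gene of any study organism"),
        ("Protein", "protein product"),
        ("Compound", "small molecule / drug"),
        ("mRNA", "transcript entry"),
    ):
        model = define_type(model, "element", ElementTypeDef(name, desc))
    for name in (DISEASE_ONTOLOGY, PROCESS_ONTOLOGY):
        model = define_type(model, "ontology", OntologyDef(name, "obo"))
    for name, sources, targets, directed in (
        ("protein interaction", {"Protein"}, {"Protein"}, False),
        ("genetic interaction", {"Gene"}, {"Gene"}, False),
        ("gene-disease association", {"Gene"}, {DISEASE_ONTOLOGY}, True),
        ("gene-compound interaction", {"Gene"}, {"Compound"}, False),
        ("is medicated by", {"Patient"}, {"Compound"}, True),
        ("is diagnosed with", {"Patient"}, {DISEASE_ONTOLOGY}, True),
        ("expressed as", {"Gene"}, {"Protein"}, True),
        ("transcribed as", {"Gene"}, {"mRNA"}, True),
        ("has function", {"Gene"}, {PROCESS_ONTOLOGY}, True),
    ):
        model = define_type(
            model,
            "relation",
            RelationTypeDef(name, frozenset(sources), frozenset(targets), directed),
        )
    model = define_type(
        model,
        "annotation_form",
        AnnotationFormDef(
            "Patient Anthropometrics",
            attributes=(
                AttributeDef("Age", "integer", required=True),
                AttributeDef(
                    "Sex", "controlled_term", required=True,
                    allowed_values=("male", "female"),
                ),
                AttributeDef("BMI-BeforeTraining", "decimal"),
                AttributeDef("BMI-BT", "decimal"),
            ),
            applicable_to=frozenset({"Patient"}),
        ),
    )
    model = define_type(
        model,
        "annotation_form",
        AnnotationFormDef(
            "Patient diagnostic data",
            attributes=(
                AttributeDef("GOLD", "integer"),
                AttributeDef("Smoking status", "integer"),
                AttributeDef("Packs per", "integer"),
            ),
            applicable_to=frozenset({"Patient"}),
        ),
    )
    model = define_type(
        model,
        "annotation_form",
        AnnotationFormDef(
            "Patient Physiology",
            attributes=(
                AttributeDef("Walk-BeforeTraining", "integer"),
                AttributeDef("Walk-AfterTraining", "integer"),
            ),
            applicable_to=frozenset({"Patient"}),
        ),
    )
    model = define_type(
        model,
        "annotation_form",
        AnnotationFormDef(
            "interaction evidence",
            attributes=(
                AttributeDef("Method", "text"),
                AttributeDef("PubMed count", "integer"),
            ),
            subforms=(
                AnnotationFormDef(
                    "provenance",
                    attributes=(AttributeDef("database", "text"),),
                ),
            ),
            applicable_to=frozenset({"protein interaction", "genetic interaction"}),
        ),
    )
    model = define_type(
        model,
        "experiment_format",
        ExperimentFormatDef(
            "Expression",
            entity_type="Gene",
            columns=(
                AttributeDef("fold_change", "decimal", required=True),
                AttributeDef("p_value", "decimal"),
            ),
        ),
    )
    for name in ("pathway", "disease process"):
        model = define_type(model, "context", ContextTypeDef(name))
    model = define_type(
        model,
        "external_source",
        ExternalSourceDef(
            "variant catalogue",
            adapter_id="tsv",
            exposed_attributes=(AttributeDef("variant", "text"),),
        ),
    )
    return model


def build_disease_ontology(size: int = 60) -> OntologyGraph:
    """Small NCI-thesaurus-like disease DAG with a cancer branch.

    The cancer branch deliberately contains terms whose names do not
    include the word "cancer" (carcinoma, neoplasm), so queries matching
    the pattern only find them through descendant inference.
    """
    base: list[tuple[str, str, tuple]] = [
        ("D:0000001", "disease", ()),
        ("D:0000002", "cancer", (("D:0000001", "is_a"),)),
        ("D:0000003", "respiratory disease", (("D:0000001", "is_a"),)),
        ("D:0000004", "metabolic disease", (("D:0000001", "is_a"),)),
        ("D:0000005", "cardiovascular disease", (("D:0000001", "is_a"),)),
        ("D:0000006", "lung cancer", (("D:0000002", "is_a"),)),
        ("D:0000007", "pancreatic carcinoma", (("D:0000002", "is_a"),)),
        ("D:0000008", "malignant neoplasm of breast", (("D:0000002", "is_a"),)),
        ("D:0000009", "small cell lung carcinoma", (("D:0000006", "is_a"),)),
        ("D:0000010", "chronic obstructive pulmonary disease", (("D:0000003", "is_a"),)),
        ("D:0000011", "asthma", (("D:0000003", "is_a"),)),
        ("D:0000012", "emphysema", (("D:0000010", "part_of"),)),
        ("D:0000013", "diabetes mellitus", (("D:0000004", "is_a"),)),
        ("D:0000014", "muscle wasting disorder", (("D:0000004", "is_a"),)),
    ]
    branch_heads = ["D:0000003", "D:0000004", "D:0000005", "D:0000006"]
    terms = {tid: OntologyTerm(DISEASE_ONTOLOGY, tid, name, parents)
             for tid, name, parents in base}
    for i in range(len(base) + 1, size + 1):
        tid = f"D:{i:07d}"
        head = branch_heads[i % len(branch_heads)]
        terms[tid] = OntologyTerm(
            DISEASE_ONTOLOGY, tid, f"disorder {i}", ((head, "is_a"),)
        )
    return OntologyGraph(DISEASE_ONTOLOGY, terms)


def build_process_ontology() -> OntologyGraph:
    """GO-like biological-process DAG with a signal transduction branch."""
    base = [
        ("P:0000001", "biological process", ()),
        ("P:0000002", "signal transduction", (("P:0000001", "is_a"),)),
        ("P:0000003", "metabolic process", (("P:0000001", "is_a"),)),
        ("P:0000004", "inflammatory response", (("P:0000001", "is_a"),)),
        ("P:0000005", "MAPK cascade", (("P:0000002", "is_a"),)),
        ("P:0000006", "TNF-mediated signaling", (("P:0000002", "is_a"),)),
        ("P:0000007", "glycolytic process", (("P:0000003", "is_a"),)),
        ("P:0000008", "oxidative phosphorylation", (("P:0000003", "is_a"),)),
        ("P:0000009", "cytokine production", (("P:0000004", "is_a"),)),
        ("P:0000010", "stress-activated kinase cascade", (("P:0000005", "is_a"),)),
    ]
    return OntologyGraph(
        PROCESS_ONTOLOGY,
        {tid: OntologyTerm(PROCESS_ONTOLOGY, tid, name, parents)
         for tid, name, parents in base},
    )


def benchmark_queries() -> dict[str, Query]:
    """The named benchmark queries, parsed and validated against the model."""
    model = build_model()
    fig3 = {
        "find": "Patient",
        "where": {
            "all": [
                {"annotated_by": {
                    "form": "Patient Anthropometrics",
                    "has": [
                        {"attribute": "Age", "op": "gt", "value": 30},
                        {"attribute": "Sex", "op": "eq", "value": "male"},
                        {"attribute": "BMI-BeforeTraining", "op": "ge", "value": 10},
                    ],
                }},
                {"annotated_by": {
                    "form": "Patient diagnostic data",
                    "has": [
                        {"attribute": "Smoking status", "op": "eq", "value": 1},
                        {"attribute": "Packs per", "op": "ge", "value": 10},
                    ],
                }},
                {"annotated_by": {
                    "form": "Patient Physiology",
                    "has": [
                        {"attribute": "Walk-AfterTraining", "op": "ge", "value": 120},
                        {"attribute": "Walk-BeforeTraining", "op": "le", "value": 100},
                    ],
                }},
            ]
        },
    }
    severe_no_cancer = {
        "find": "Patient",
        "where": {
            "all": [
                {"annotated_by": {
                    "form": "Patient diagnostic data",
                    "has": [{"attribute": "GOLD", "op": "gt",
                             "value": {"var": "gold_min"}}],
                }},
                {"annotated_by": {
                    "form": "Patient Anthropometrics",
                    "has": [{"attribute": "BMI-BT", "op": "lt",
                             "value": {"var": "bmi_max"}}],
                }},
                {"never": {
                    "ontology_linked": {
                        "relation": "is diagnosed with",
                        "ontology": DISEASE_ONTOLOGY,
                        "name_like": "*cancer*",
                    }
                }},
            ]
        },
        "variables": {
            "gold_min": {"kind": "integer", "default": 2},
            "bmi_max": {"kind": "decimal", "default": 18},
        },
    }
    signalling_genes = {
        "find": "Gene",
        "where": {
            "all": [
                {"any": [
                    {"has_experiment_value": {
                        "format": "Expression",
                        "label_like": "*COPD*",
                        "has": [{"attribute": "fold_change", "op": "lt", "value": -1.0}],
                    }},
                    {"has_experiment_value": {
                        "format": "Expression",
                        "label_like": "*COPD*",
                        "has": [{"attribute": "fold_change", "op": "gt", "value": 1.0}],
                    }},
                ]},
                {"ontology_linked": {
                    "relation": "has function",
                    "ontology": PROCESS_ONTOLOGY,
                    "name_like": "signal transduction",
                }},
            ]
        },
    }
    return {
        "fig3-patient-training": parse_query(fig3, model),
        "severe-low-bmi-no-cancer": parse_query(severe_no_cancer, model),
        "responsive-signalling-genes": parse_query(signalling_genes, model),
    }


def fixture_search_config() -> SearchConfig:
    """The designated seed-connection parameter set for the fixture KB.

    Allows the interaction-evidence relation types plus the gene→protein
    expression link as the bridge between the protein and the
    gene/compound layer; gene–disease hops are penalised twice as much
    as direct physical evidence.
    """
    return SearchConfig(
        allowed_relation_types=frozenset({
            "protein interaction",
            "genetic interaction",
            "gene-compound interaction",
            "gene-disease association",
            "expressed as",
        }),
        penalty={"gene-disease association": 2.0},
        undirected=True,
    )


def _oracle_pairwise_costs(kb: KnowledgeBase, seeds, config: SearchConfig) -> dict:
    """Library shortest-path oracle, independent of the package's search."""
    g = nx.Graph()
    for rel in kb.relations.values():
        if rel.type not in config.allowed_relation_types:
            continue
        w = config.weight(rel.type)
        a, b = rel.source, rel.target
        if g.has_edge(a, b):
            w = min(w, g[a][b]["weight"])
        g.add_edge(a, b, weight=w)
    costs = {}
    seeds = sorted(seeds, key=lambda r: r.id)
    for i, a in enumerate(seeds):
        for b in seeds[i + 1:]:
            try:
                cost = nx.dijkstra_path_length(g, a, b)
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                cost = float("inf")
            costs[(a.id, b.id)] = cost
    return costs


def generate_kb(spec: FixtureSpec = FixtureSpec()) -> tuple[KnowledgeBase, GroundTruth]:
    """Generate the synthetic knowledge base and its oracle ground truth."""
    rng = random.Random(spec.seed)
    kb = KnowledgeBase(build_model())
    kb.attach_ontology(build_disease_ontology(spec.ontology_size))
    kb.attach_ontology(build_process_ontology())

    disease = kb.ontologies[DISEASE_ONTOLOGY]
    cancer_terms = sorted(
        {"D:0000002"}
        | {t for t in disease.terms if _is_descendant(disease, t, "D:0000002")}
    )
    non_cancer_terms = sorted(set(disease.terms) - set(cancer_terms) - {"D:0000001"})
    process = kb.ontologies[PROCESS_ONTOLOGY]
    signalling = sorted(
        {"P:0000002"}
        | {t for t in process.terms if _is_descendant(process, t, "P:0000002")}
    )
    other_processes = sorted(set(process.terms) - set(signalling) - {"P:0000001"})

    genes = []
    for i in range(spec.n_genes):
        name = "MAPK14" if i == 0 else f"GENE{i + 1}"
        accession = "1432" if i == 0 else str(1000 + i)
        genes.append(kb.create_element("Gene", name, [("EntrezGene", accession)]))
    proteins = [
        kb.create_element("Protein", f"PROT{i + 1}", [("UniProt", f"P{10000 + i}")])
        for i in range(spec.n_proteins)
    ]
    compounds = [
        kb.create_element("Compound", f"CPD{i + 1}", [("ChEBI", str(20000 + i))])
        for i in range(spec.n_compounds)
    ]
    patients = [
        kb.create_element("Patient", f"P{i + 1:04d}", [("BioBridgeID", f"PT{i + 1:04d}")])
        for i in range(spec.n_patients)
    ]

    # gene -> protein expression links (1:1 where both exist)
    for g, p in zip(genes, proteins):
        kb.create_relation("expressed as", g, p)

    # protein interaction network: random + a planted backbone so the
    # designated seed set is connected
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if rng.random() < spec.interaction_density:
                kb.create_relation("protein interaction", proteins[i], proteins[j])
    seeds: list[ObjectRef] = []
    if len(proteins) >= 8 and len(compounds) >= 4 and len(genes) >= 7:
        p_a, p_b, bridge = proteins[1], proteins[6], proteins[3]
        c_a, c_b = compounds[0], compounds[2]
        seeds = [p_a, p_b, c_a, c_b]
        for a, b in ((p_a, bridge), (bridge, p_b)):
            if kb.find_relation("protein interaction", a, b) is None:
                kb.create_relation("protein interaction", a, b)
        # compound path: c_a - gene5 - gene6 - c_b, bridged to the protein
        # layer through gene4 "expressed as" proteins[3]
        for rel_type, a, b in (
            ("gene-compound interaction", genes[4], c_a),
            ("genetic interaction", genes[4], genes[5]),
            ("gene-compound interaction", genes[5], c_b),
            ("gene-compound interaction", genes[3], c_a),
        ):
            if kb.find_relation(rel_type, a, b) is None:
                kb.create_relation(rel_type, a, b)

    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.random() < spec.interaction_density / 2:
                if kb.find_relation("genetic interaction", genes[i], genes[j]) is None:
                    kb.create_relation("genetic interaction", genes[i], genes[j])

    for g in genes:
        if rng.random() < 0.3 and non_cancer_terms:
            term = kb.term_ref(DISEASE_ONTOLOGY, rng.choice(non_cancer_terms))
            kb.create_relation("gene-disease association", g, term)
        if rng.random() < 0.25 and compounds:
            c = rng.choice(compounds)
            if kb.find_relation("gene-compound interaction", g, c) is None:
                kb.create_relation("gene-compound interaction", g, c)
        n_functions = rng.randint(1, 2)
        pool = signalling if rng.random() < 0.3 else other_processes
        for term_id in rng.sample(pool, min(n_functions, len(pool))):
            term = kb.term_ref(PROCESS_ONTOLOGY, term_id)
            if kb.find_relation("has function", g, term) is None:
                kb.create_relation("has function", g, term)

    # patients: annotation forms + diagnoses + medication
    for p in patients:
        age = rng.randint(25, 80)
        sex = rng.choice(["male", "female"])
        bmi = round(rng.gauss(24.0, 6.0), 1)
        kb.attach_annotation(
            "Patient Anthropometrics",
            {"Age": age, "Sex": sex, "BMI-BeforeTraining": bmi, "BMI-BT": bmi},
            [p],
        )
        kb.attach_annotation(
            "Patient diagnostic data",
            {
                "GOLD": rng.randint(0, 4),
                "Smoking status": 1 if rng.random() < 0.6 else 0,
                "Packs per": rng.randint(0, 40),
            },
            [p],
        )
        walk_before = rng.randint(60, 130)
        kb.attach_annotation(
            "Patient Physiology",
            {
                "Walk-BeforeTraining": walk_before,
                "Walk-AfterTraining": walk_before + rng.randint(0, 80),
            },
            [p],
        )
        r = rng.random()
        if r < 0.2 and cancer_terms:
            term_id = rng.choice([t for t in cancer_terms if t != "D:0000002"])
            kb.create_relation(
                "is diagnosed with", p, kb.term_ref(DISEASE_ONTOLOGY, term_id)
            )
        elif r < 0.8 and non_cancer_terms:
            kb.create_relation(
                "is diagnosed with",
                p,
                kb.term_ref(DISEASE_ONTOLOGY, rng.choice(non_cancer_terms)),
            )
        if rng.random() < 0.5 and compounds:
            c = rng.choice(compounds)
            if kb.find_relation("is medicated by", p, c) is None:
                kb.create_relation("is medicated by", p, c)

    # expression experiment over all genes
    if genes:
        rows = []
        for g in genes:
            fold = round(rng.gauss(0.0, 0.8), 2)
            rows.append((g, {"fold_change": fold, "p_value": round(rng.random(), 3)}))
        kb.record_experiment("Expression", EXPRESSION_LABEL, rows)

    # contexts: pathways over genes/proteins, disease processes over proteins
    molecule_pool = genes + proteins
    for i in range(spec.n_pathways):
        size = rng.randint(5, min(10, max(5, len(molecule_pool))))
        members = rng.sample(molecule_pool, min(size, len(molecule_pool)))
        kb.build_context("pathway", f"KEGG-like pathway {i + 1}", members)
    for i in range(4):
        if not proteins:
            break
        members = rng.sample(proteins, min(rng.randint(3, 8), len(proteins)))
        kb.build_context(
            "disease process", f"COPD inflammatory process {i + 1}", members
        )

    # ground truth via the independent oracles
    truth = GroundTruth()
    for name, query in benchmark_queries().items():
        bound = bind_variables(query, {}) if query.variables else query
        truth.satisfying_patients[name] = tuple(
            r.id for r in brute_force_evaluate(kb, bound)
        )
    if seeds:
        truth.seed_ids = tuple(s.id for s in seeds)
        truth.pairwise_path_costs = _oracle_pairwise_costs(
            kb, seeds, fixture_search_config()
        )
    return kb, truth


def _is_descendant(graph: OntologyGraph, term_id: str, ancestor: str) -> bool:
    frontier = [term_id]
    seen = set()
    while frontier:
        current = frontier.pop()
        for parent, _label in graph.terms[current].parents:
            if parent == ancestor:
                return True
            if parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    return False


# ---------------------------------------------------------------------------
# random structures for oracle cross-checks
# ---------------------------------------------------------------------------

_ATTRIBUTE_POOLS = {
    "Patient Anthropometrics": [
        ("Age", "integer", (20, 85)),
        ("BMI-BeforeTraining", "decimal", (10.0, 40.0)),
        ("BMI-BT", "decimal", (10.0, 40.0)),
    ],
    "Patient diagnostic data": [
        ("GOLD", "integer", (0, 4)),
        ("Smoking status", "integer", (0, 1)),
        ("Packs per", "integer", (0, 40)),
    ],
    "Patient Physiology": [
        ("Walk-BeforeTraining", "integer", (50, 140)),
        ("Walk-AfterTraining", "integer", (50, 220)),
    ],
}


def _random_comparison(rng: random.Random, form: str) -> dict:
    attr, kind, (lo, hi) = rng.choice(_ATTRIBUTE_POOLS[form])
    op = rng.choice(["gt", "ge", "lt", "le", "eq", "ne"])
    value = rng.randint(lo, hi) if kind == "integer" else round(rng.uniform(lo, hi), 1)
    return {"attribute": attr, "op": op, "value": value}


def _random_leaf(rng: random.Random, target: str) -> dict:
    if target == "Gene":
        kind = rng.choice(
            ["related_via", "ontology_linked", "in_context", "has_experiment_value"]
        )
        if kind == "related_via":
            return {"related_via": {
                "relation": rng.choice(
                    ["genetic interaction", "expressed as",
                     "gene-compound interaction"]),
                "direction": rng.choice(["out", "in", "any"]),
            }}
        if kind == "ontology_linked":
            return {"ontology_linked": {
                "relation": rng.choice(
                    ["has function", "gene-disease association"]),
                "name_like": rng.choice(
                    ["signal", "process", "disease", "cancer", "metabolic"]),
            }}
        if kind == "in_context":
            return {"in_context": {
                "context_type": "pathway",
                "name_like": rng.choice([None, "KEGG", "pathway 1"]),
            }}
        return {"has_experiment_value": {
            "format": "Expression",
            "label_like": rng.choice([None, "*COPD*"]),
            "has": [{
                "attribute": "fold_change",
                "op": rng.choice(["gt", "lt", "ge", "le"]),
                "value": round(rng.uniform(-1.5, 1.5), 2),
            }],
        }}
    kind = rng.choice(["annotated_by", "annotated_by", "related_via",
                       "ontology_linked", "in_context"])
    if kind == "annotated_by":
        form = rng.choice(list(_ATTRIBUTE_POOLS))
        return {"annotated_by": {
            "form": form,
            "has": [_random_comparison(rng, form)
                    for _ in range(rng.randint(1, 2))],
        }}
    if kind == "related_via":
        return {"related_via": {
            "relation": rng.choice(["is medicated by", "is diagnosed with"]),
            "direction": "out",
        }}
    if kind == "ontology_linked":
        return {"ontology_linked": {
            "relation": "is diagnosed with",
            "name_like": rng.choice(
                ["cancer", "respiratory", "disease", "disorder"]),
        }}
    return {"in_context": {"context_type": "pathway"}}


def random_query_mapping(rng: random.Random, depth: int = 3) -> dict:
    """A random declarative query over the fixture model (clause depth <= depth).

    Used by the oracle-equivalence checks: queries mix annotation
    comparisons, relation chains, ontology inference, context membership
    and experiment-value predicates under random and/or/not combinators.
    """
    target = rng.choice(["Patient", "Gene"])

    def clause(d: int) -> dict:
        if d <= 0 or rng.random() < 0.4:
            return _random_leaf(rng, target)
        combinator = rng.choice(["all", "any", "not"])
        if combinator == "not":
            return {"not": clause(d - 1)}
        return {combinator: [clause(d - 1) for _ in range(rng.randint(2, 3))]}

    return {"find": target, "where": clause(depth)}


def random_query(rng: random.Random, model: DataModel, depth: int = 3) -> Query:
    return parse_query(random_query_mapping(rng, depth), model)


def random_dag_terms(rng: random.Random, n_terms: int) -> dict:
    """Random rooted DAG as OntologyTerm mapping; parents point at lower ids."""
    terms = {}
    for i in range(n_terms):
        tid = f"T:{i:04d}"
        if i == 0:
            parents = ()
        else:
            k = min(i, rng.choice([1, 1, 1, 2, 2, 3]))
            chosen = rng.sample(range(i), k)
            parents = tuple(
                (f"T:{j:04d}", rng.choice(["is_a", "part_of"]))
                for j in sorted(chosen)
            )
        terms[tid] = OntologyTerm("random", tid, f"term {i}", parents)
    return terms


# ---------------------------------------------------------------------------
# synthetic full-scale model export (foreign tag vocabulary)
# ---------------------------------------------------------------------------

#: Profile mapping the synthetic foreign export vocabulary onto the dialect.
SCALED_EXPORT_PROFILE = TagProfile(
    sections={
        "objects": "element-types",
        "associations": "relation-types",
        "record-forms": "annotation-forms",
        "assays": "experiment-formats",
        "subnetworks": "context-types",
        "vocabularies": "ontologies",
        "externals": "external-sources",
    },
    items={
        "object": "element-type",
        "association": "relation-type",
        "record-form": "annotation-form",
        "assay": "experiment-format",
        "subnetwork": "context-type",
        "vocabulary": "ontology",
        "external": "external-source",
        "from": "source",
        "to": "target",
        "field": "attribute",
        "measure": "column",
        "applies": "applies-to",
        "subrecord": "subform",
        "choice": "allowed",
    },
    fields={"label": "name", "datatype": "kind"},
)

_INVERSE_TAGS = {
    **{v: k for k, v in SCALED_EXPORT_PROFILE.sections.items()},
    **{v: k for k, v in SCALED_EXPORT_PROFILE.items.items()},
}
_INVERSE_FIELDS = {v: k for k, v in SCALED_EXPORT_PROFILE.fields.items()}


def synthetic_scaled_model_export(
    n_element_types: int = 15,
    n_relation_types: int = 82,
    n_annotation_forms: int = 61,
    n_attributes: int = 892,
    n_experiment_formats: int = 7,
    n_context_types: int = 16,
    n_ontologies: int = 19,
) -> bytes:
    """A *synthetic* stand-in for a full-scale model export.

    Builds a data model at the configuration scale of a mature chronic
    disease knowledge base (element/relation/form/format/context/ontology
    counts as given), serialises it, and rewrites the document into a
    foreign tag vocabulary that only parses through
    :data:`SCALED_EXPORT_PROFILE`.  The content is generated, not real —
    it exercises the profile machinery and category counting at realistic
    scale.
    """
    from lxml import etree

    model = DataModel()
    element_names = [
        "Patient", "Gene", "Protein", "Compound", "mRNA", "Disease term",
        "Sequence Variant", "Tissue", "Cell type", "Organ", "Pathway model",
        "Literature reference", "Clinical study", "Probe", "Metabolite",
    ][:n_element_types]
    while len(element_names) < n_element_types:
        element_names.append(f"Entity {len(element_names) + 1}")
    for name in element_names:
        model = define_type(model, "element", ElementTypeDef(name))
    for i in range(n_ontologies):
        model = define_type(model, "ontology", OntologyDef(f"ontology {i + 1}"))
    for i in range(n_context_types):
        model = define_type(model, "context", ContextTypeDef(f"context type {i + 1}"))
    endpoints = element_names + [f"ontology {i + 1}" for i in range(n_ontologies)]
    for i in range(n_relation_types):
        src = endpoints[i % len(element_names)]
        tgt = endpoints[(i * 7 + 3) % len(endpoints)]
        model = define_type(
            model,
            "relation",
            RelationTypeDef(
                f"relation type {i + 1}", frozenset({src}), frozenset({tgt}),
                directed=bool(i % 2),
            ),
        )
    per_form = n_attributes // n_annotation_forms
    remainder = n_attributes - per_form * n_annotation_forms
    for i in range(n_annotation_forms):
        count = per_form + (1 if i < remainder else 0)
        attrs = tuple(
            AttributeDef(f"attribute {j + 1}",
                         ("text", "integer", "decimal")[j % 3])
            for j in range(count)
        )
        model = define_type(
            model,
            "annotation_form",
            AnnotationFormDef(
                f"form {i + 1}", attributes=attrs,
                applicable_to=frozenset({element_names[i % len(element_names)]}),
            ),
        )
    for i in range(n_experiment_formats):
        model = define_type(
            model,
            "experiment_format",
            ExperimentFormatDef(
                f"experiment format {i + 1}",
                entity_type=element_names[i % len(element_names)],
                columns=(AttributeDef("value", "decimal", required=True),),
            ),
        )
    document = write_model_xml(model)
    root = etree.fromstring(document)
    for node in root.iter():
        if node.tag in _INVERSE_TAGS:
            node.tag = _INVERSE_TAGS[node.tag]
        for attr in list(node.attrib):
            if attr in _INVERSE_FIELDS:
                node.attrib[_INVERSE_FIELDS[attr]] = node.attrib.pop(attr)
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
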