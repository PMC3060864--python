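"""Penalty-weighted seed connection, layers, expansion."""

import itertools
import math
import random

import pytest

from semkb.fixtures import (
    FixtureSpec,
    fixture_search_config,
    generate_kb,
)
from semkb.network import (
    LayerSpec,
    NetworkError,
    SearchConfig,
    Subnetwork,
    apply_information_layer,
    connect_seeds,
    expand,
    export_subnetwork_graphml,
    export_subnetwork_tsv,
)
from semkb.report import ViewItem
from semkb.schema import (
    DataModel,
    ElementTypeDef,
    RelationTypeDef,
    define_type,
)
from semkb.store import KnowledgeBase


def _graph_model(relation_types=("edgeA", "edgeB")):
    model = define_type(DataModel(), "element", ElementTypeDef("Node"))
    for rt in relation_types:
        model = define_type(
            model, "relation",
            RelationTypeDef(rt, {"Node"}, {"Node"}, directed=False),
        )
    return model


def _random_graph_kb(rng, n_nodes, edge_prob=0.4):
    kb = KnowledgeBase(_graph_model())
    nodes = [kb.create_element("Node", f"N{i}", []) for i in range(n_nodes)]
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < edge_prob:
            kb.create_relation(rng.choice(["edgeA", "edgeB"]), nodes[i], nodes[j])
    return kb, nodes


def _enumerate_best_cost(kb, config, a, b):
    """Exhaustive simple-path enumeration oracle (graphs <= 12 nodes)."""
    adj = {}
    for rel in kb.relations.values():
        if rel.type not in config.allowed_relation_types:
            continue
        w = config.weight(rel.type)
        adj.setdefault(rel.source, []).append((rel.target, w))
        adj.setdefault(rel.target, []).append((rel.source, w))
    best = math.inf

    def walk(node, cost, visited):
        nonlocal best
        if node == b:
            best = min(best, cost)
            return
        for nbr, w in adj.get(node, ()):
            if nbr not in visited:
                walk(nbr, cost + w, visited | {nbr})

    walk(a, 0.0, {a})
    return best


def test_three_edge_chain_cost_and_node_count():
    kb = KnowledgeBase(_graph_model())
    nodes = [kb.create_element("Node", f"N{i}", []) for i in range(4)]
    for a, b in zip(nodes, nodes[1:]):
        kb.create_relation("edgeA", a, b)
    config = SearchConfig(allowed_relation_types={"edgeA"})
    subnet = connect_seeds(kb, [nodes[0], nodes[3]], config)
    assert subnet.path_costs[frozenset((nodes[0], nodes[3]))] == 3.0
    assert len(subnet.nodes) == 4 and len(subnet.edges) == 3


def test_unreachable_pair_reported_with_infinite_cost():
    kb = KnowledgeBase(_graph_model())
    a = kb.create_element("Node", "a", [])
    b = kb.create_element("Node", "b", [])
    config = SearchConfig(allowed_relation_types={"edgeA"})
    subnet = connect_seeds(kb, [a, b], config)
    assert subnet.path_costs[frozenset((a, b))] == math.inf
    assert subnet.nodes == {a, b} and subnet.edges == frozenset()


def test_nonpositive_penalty_and_empty_allowed_set_rejected():
    with pytest.raises(NetworkError, match="non-empty"):
        SearchConfig(allowed_relation_types=set())
    with pytest.raises(NetworkError, match="positive"):
        SearchConfig(allowed_relation_types={"edgeA"}, penalty={"edgeA": 0.0})


@pytest.mark.parametrize("trial", range(25))
def test_pairwise_costs_equal_exhaustive_enumeration(trial):
    rng = random.Random(7000 + trial)
    kb, nodes = _random_graph_kb(rng, rng.randint(4, 12))
    config = SearchConfig(
        allowed_relation_types={"edgeA", "edgeB"},
        penalty={"edgeA": rng.choice([0.5, 1.0, 2.0]),
                 "edgeB": rng.choice([1.0, 1.5, 3.0])},
    )
    seeds = rng.sample(nodes, rng.randint(2, min(4, len(nodes))))
    subnet = connect_seeds(kb, seeds, config)
    for pair, cost in subnet.path_costs.items():
        a, b = sorted(pair, key=lambda r: r.id)
        assert cost == pytest.approx(_enumerate_best_cost(kb, config, a, b))


def test_penalty_monotonicity_under_sweep():
    rng = random.Random(31)
    kb, nodes = _random_graph_kb(rng, 10)
    seeds = nodes[:3]
    previous = None
    for step in range(10):
        config = SearchConfig(
            allowed_relation_types={"edgeA", "edgeB"},
            penalty={"edgeA": 1.0 + 0.5 * step},
        )
        costs = connect_seeds(kb, seeds, config).path_costs
        if previous is not None:
            for pair, cost in costs.items():
                assert cost >= previous[pair] - 1e-12
        previous = costs


def test_subnetwork_closure_every_edge_endpoint_included():
    rng = random.Random(55)
    kb, nodes = _random_graph_kb(rng, 10)
    config = SearchConfig(allowed_relation_types={"edgeA", "edgeB"})
    subnet = connect_seeds(kb, nodes[:4], config)
    for edge in subnet.edges:
        rel = kb.relations[edge.id]
        assert rel.source in subnet.nodes and rel.target in subnet.nodes


def test_tie_break_is_deterministic():
    # two equal-cost paths a-b-d and a-c-d: the smaller node-id sequence wins
    kb = KnowledgeBase(_graph_model())
    a = kb.create_element("Node", "a", [])
    b = kb.create_element("Node", "b", [])
    c = kb.create_element("Node", "c", [])
    d = kb.create_element("Node", "d", [])
    for x, y in ((a, b), (b, d), (a, c), (c, d)):
        kb.create_relation("edgeA", x, y)
    config = SearchConfig(allowed_relation_types={"edgeA"})
    subnet = connect_seeds(kb, [a, d], config)
    assert subnet.nodes == {a, b, d}  # b has the smaller id than c


def test_fixture_seed_connection_matches_recorded_oracle_costs(small_kb):
    kb, truth = small_kb
    from semkb.store import ObjectRef

    seeds = [ObjectRef("element", i) for i in truth.seed_ids]
    subnet = connect_seeds(kb, seeds, fixture_search_config())
    got = {
        tuple(sorted(r.id for r in pair)): cost
        for pair, cost in subnet.path_costs.items()
    }
    assert got == truth.pairwise_path_costs


def test_expand_adds_one_step_neighbors_and_reaches_fixpoint(small_kb):
    kb, _ = small_kb
    gene = kb.elements_of_type("Gene")[0]
    subnet = Subnetwork(nodes={gene.ref}, seed_nodes={gene.ref})
    grown = expand(kb, subnet, ["gene-compound interaction"])
    for edge in grown.edges:
        rel = kb.relations[edge.id]
        assert rel.type == "gene-compound interaction"
    # idempotent once the fixed point is reached
    full = grown
    while True:
        nxt = expand(kb, full, ["gene-compound interaction"])
        if nxt.nodes == full.nodes and nxt.edges == full.edges:
            break
        full = nxt
    again = expand(kb, full, ["gene-compound interaction"])
    assert again.nodes == full.nodes and again.edges == full.edges


def test_expand_unknown_relation_type_rejected(small_kb):
    kb, _ = small_kb
    subnet = Subnetwork()
    with pytest.raises(Exception, match="teleports"):
        expand(kb, subnet, ["teleports"])


def test_information_layer_assigns_every_node_exactly_one_bin(small_kb):
    kb, truth = small_kb
    from semkb.store import ObjectRef

    seeds = [ObjectRef("element", i) for i in truth.seed_ids]
    subnet = connect_seeds(kb, seeds, fixture_search_config())
    spec = LayerSpec(
        view_item=ViewItem(
            "disease pathways", "context_membership",
            context_type="disease process", aggregate="count",
        ),
        channel="color",
        numeric_breaks=(1, 3, 6),
        bin_labels=("pale", "light red", "red", "deep red"),
        missing_bin="grey",
    )
    styled = apply_information_layer(kb, subnet, spec)
    assert set(styled.styles) == set(styled.nodes)
    assert all("color" in s for s in styled.styles.values())


def test_layer_bins_are_half_open():
    spec = LayerSpec(
        view_item=None, numeric_breaks=(1, 3), bin_labels=("low", "mid", "high")
    )
    assert spec.bin_for(0) == "low"
    assert spec.bin_for(1) == "mid"  # boundary joins the upper bin
    assert spec.bin_for(2.99) == "mid"
    assert spec.bin_for(3) == "high"
    assert spec.bin_for(None) == "missing"


def test_layer_rejects_non_monotone_breaks():
    with pytest.raises(NetworkError, match="increasing"):
        LayerSpec(view_item=None, numeric_breaks=(3, 1), bin_labels=("a", "b", "c"))


def test_all_missing_values_land_in_missing_bin():
    kb = KnowledgeBase(_graph_model())
    a = kb.create_element("Node", "a", [])
    b = kb.create_element("Node", "b", [])
    kb.create_relation("edgeA", a, b)
    subnet = connect_seeds(kb, [a, b], SearchConfig(allowed_relation_types={"edgeA"}))
    spec = LayerSpec(
        view_item=ViewItem("none", "own_attribute", form="missing-form",
                           attribute="missing"),
        numeric_breaks=(1,), bin_labels=("lo", "hi"), missing_bin="grey",
    )
    styled = apply_information_layer(kb, subnet, spec)
    assert all(s["color"] == "grey" for s in styled.styles.values())


def test_exports_are_deterministic(small_kb):
    kb, truth = small_kb
    from semkb.store import ObjectRef

    seeds = [ObjectRef("element", i) for i in truth.seed_ids]
    subnet = connect_seeds(kb, seeds, fixture_search_config())
    nodes_tsv, edges_tsv = export_subnetwork_tsv(kb, subnet)
    assert nodes_tsv.splitlines()[0].startswith("id\tkind")
    assert (export_subnetwork_tsv(kb, subnet) ==
            (nodes_tsv, edges_tsv))
    assert (export_subnetwork_graphml(kb, subnet) ==
            export_subnetwork_graphml(kb, subnet))
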