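"""Core (k,l)-pebble game: acceptance rule, invariants, components."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rigidkit.fixtures import er_graph, laman_graph
from rigidkit.oracle import brute_force_sparse
from rigidkit.pebble import (
    LoopError,
    Multigraph,
    ParameterError,
    SparsityParams,
    new_game,
    play_component_game,
    play_game,
)

P23 = SparsityParams(2, 3)


def triangle():
    return Multigraph.from_edges([(0, 1, 1), (1, 2, 1), (0, 2, 1)])


# -- parameters -------------------------------------------------------------


def test_valid_parameter_range():
    SparsityParams(1, 0)
    SparsityParams(2, 3)
    SparsityParams(6, 6)
    with pytest.raises(ParameterError):
        SparsityParams(0, 0)
    with pytest.raises(ParameterError):
        SparsityParams(2, -1)
    with pytest.raises(ParameterError):
        SparsityParams(2, 4)  # Maxwell boundary needs explicit opt-in
    SparsityParams(2, 4, boundary=True)
    with pytest.raises(ParameterError):
        SparsityParams(2, 5, boundary=True)


# -- small worked examples --------------------------------------------------


def test_triangle_is_23_tight():
    s = play_game(triangle(), P23)
    assert s.category == "tight"
    assert s.free_pebbles == 3
    assert s.accepted_count == 3
    assert s.rejected_edges == []


def test_k4_is_23_spanning_with_one_rejection():
    edges = [(u, v, 1) for u in range(4) for v in range(u + 1, 4)]
    s = play_game(Multigraph.from_edges(edges), P23)
    assert s.category == "spanning"
    assert len(s.rejected_edges) == 1
    assert s.accepted_count == 5


def test_path_is_sparse_not_tight():
    s = play_game(Multigraph.from_edges([(0, 1, 1), (1, 2, 1)]), P23)
    assert s.category == "sparse"
    assert s.free_pebbles == 4


def test_disconnected_overconstrained_is_other():
    # two K4s: each rejects an edge, graph is not spanning a single component
    edges = [(u, v, 1) for u in range(4) for v in range(u + 1, 4)]
    edges += [(u + 4, v + 4, 1) for u in range(4) for v in range(u + 1, 4)]
    s = play_game(Multigraph.from_edges(edges), P23)
    assert s.category == "other"
    assert len(s.rejected_edges) == 2


def test_duplicate_edge_handling():
    # (2,3): at most one copy of any edge between two vertices is independent
    g = new_game([0, 1], P23)
    assert g.try_insert_edge(0, 1).accepted
    assert not g.try_insert_edge(0, 1).accepted
    # (2,2) allows doubled edges, triple is rejected
    g = new_game([0, 1], SparsityParams(2, 2))
    assert g.try_insert_edge(0, 1, multiplicity=2).accepted
    assert not g.try_insert_edge(0, 1).accepted


def test_loop_rules():
    # loops carry k - l copies at most; forbidden when l >= k
    g = new_game([0], SparsityParams(3, 1))
    assert g.try_insert_edge(0, 0).accepted
    assert g.try_insert_edge(0, 0).accepted
    assert not g.try_insert_edge(0, 0).accepted
    with pytest.raises(LoopError):
        new_game([0], P23).try_insert_edge(0, 0)


# -- invariants -------------------------------------------------------------


def edge_list_strategy():
    return st.lists(
        st.tuples(st.integers(0, 7), st.integers(0, 7)).filter(lambda e: e[0] != e[1]),
        min_size=0,
        max_size=24,
    )


def params_strategy():
    return st.tuples(st.integers(1, 4), st.integers(0, 7)).filter(
        lambda kl: kl[1] < 2 * kl[0]
    )


@settings(max_examples=60, deadline=None)
@given(edge_list_strategy(), params_strategy())
def test_pebble_conservation_audit(edges, kl):
    params = SparsityParams(*kl)
    g = new_game(range(8), params)
    for u, v in edges:
        g.try_insert_edge(u, v)
        g.audit()  # raises on any conservation violation


@settings(max_examples=40, deadline=None)
@given(edge_list_strategy(), params_strategy())
def test_accepted_subgraph_is_sparse(edges, kl):
    params = SparsityParams(*kl)
    g = new_game(range(8), params)
    for u, v in edges:
        g.try_insert_edge(u, v)
    assert brute_force_sparse(g.accepted_multigraph(), params)


@settings(max_examples=30, deadline=None)
@given(edge_list_strategy(), params_strategy())
def test_rejected_edges_would_break_sparsity(edges, kl):
    params = SparsityParams(*kl)
    g = new_game(range(8), params)
    for u, v in edges:
        res = g.try_insert_edge(u, v)
        if not res.accepted:
            accepted = g.accepted_multigraph()
            augmented = Multigraph.from_edges(
                accepted.edges + [(u, v, 1)], vertices=accepted.vertices
            )
            assert not brute_force_sparse(augmented, params)


def test_order_independence_of_summary_and_components():
    rng = random.Random(11)
    graph = er_graph(12, 0.45, seed=7)
    base = None
    for _ in range(20):
        edges = graph.edges[:]
        rng.shuffle(edges)
        shuffled = Multigraph.from_edges(edges, vertices=graph.vertices)
        summary, comps = play_component_game(shuffled, P23)
        family = frozenset(frozenset(c.vertex_ids) for c in comps)
        key = (summary.category, summary.free_pebbles, summary.accepted_count, family)
        if base is None:
            base = key
        assert key == base


# -- components -------------------------------------------------------------


def test_two_triangles_two_components():
    edges = [(0, 1, 1), (1, 2, 1), (0, 2, 1), (3, 4, 1), (4, 5, 1), (3, 5, 1)]
    _, comps = play_component_game(Multigraph.from_edges(edges), P23)
    families = sorted(sorted(c.vertex_ids) for c in comps)
    assert families == [[0, 1, 2], [3, 4, 5]]


def test_component_merging_via_shared_edge():
    # bowtie plus a brace: two triangles sharing vertex 2, then edges that
    # rigidify the whole — components must merge into one
    edges = [(0, 1, 1), (1, 2, 1), (0, 2, 1), (2, 3, 1), (3, 4, 1), (2, 4, 1)]
    _, comps = play_component_game(Multigraph.from_edges(edges), P23)
    assert len(comps) == 2
    edges += [(1, 3, 1), (0, 4, 1)]
    _, comps = play_component_game(Multigraph.from_edges(edges), P23)
    assert len(comps) == 1
    assert sorted(comps[0].vertex_ids) == [0, 1, 2, 3, 4]


def test_components_are_vertex_maximal_tight():
    # every reported component must itself be tight, and no strict vertex
    # superset within the graph may be tight
    graph = er_graph(9, 0.5, seed=3)
    _, comps = play_component_game(graph, P23)
    for comp in comps:
        vs = set(comp.vertex_ids)
        sub = Multigraph.from_edges(
            [(u, v, m) for u, v, m in graph.edges if u in vs and v in vs],
            vertices=sorted(vs),
        )
        s = play_game(sub, P23)
        assert s.category in ("tight", "spanning")
        assert s.free_pebbles == 3


def test_upper_range_components_can_share_one_vertex():
    # (3,4): two bodies hinged at a shared vertex each form a component
    params = SparsityParams(3, 4)
    tri = lambda a, b, c: [(a, b, 2), (b, c, 2), (a, c, 1)]  # 5 = 3*3-4 edges
    edges = tri(0, 1, 2) + tri(2, 3, 4)
    _, comps = play_component_game(Multigraph.from_edges(edges), params)
    families = sorted(sorted(c.vertex_ids) for c in comps)
    assert families == [[0, 1, 2], [2, 3, 4]]


def test_laman_round_trip():
    for seed in range(5):
        graph = laman_graph(20, seed=seed)
        summary, comps = play_component_game(graph, P23)
        assert summary.category == "tight"
        assert len(comps) == 1
        assert sorted(comps[0].vertex_ids, key=str) == sorted(
            graph.vertices, key=str
        )


def test_state_dump_reports_weights_and_pebbles():
    g = new_game([0, 1, 2], P23)
    g.try_insert_edge(0, 1)
    dump = g.state_dump()
    placed = sum(w for _, _, w in dump["weights"])
    assert sum(dump["pebbles"].values()) + placed == 2 * 3
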