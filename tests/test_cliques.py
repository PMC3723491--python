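from itertools import combinations

import numpy as np
import pytest

from voxcoex import (
    ValidationError,
    clique_min_coexpression,
    component_size_curves,
    connected_components,
    extend_clique,
    is_clique,
    seed_cliques,
    threshold_graph,
)
from voxcoex.coexpression import CoexpressionMatrix


def matrix_from_values(values):
    values = np.asarray(values, dtype=float)
    return CoexpressionMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])], values=values
    )


def random_matrix(rng, n):
    """Random symmetric matrix in [0,1] with unit diagonal (not necessarily
    a true cosine Gram matrix; the graph operations only need the contract)."""
    raw = rng.random((n, n))
    values = (raw + raw.T) / 2
    np.fill_diagonal(values, 1.0)
    return matrix_from_values(values)


# independent oracles --------------------------------------------------------

def brute_force_components(adjacency):
    """Reachability by repeated boolean matrix closure."""
    n = adjacency.shape[0]
    reach = adjacency | np.eye(n, dtype=bool)
    for _ in range(n):
        reach = reach | (reach @ reach)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        comp = sorted(np.nonzero(reach[i])[0].tolist())
        seen.update(comp)
        comps.append(comp)
    return comps


def brute_force_maximal_cliques(adjacency, min_size=2):
    """All maximal cliques by exhaustive subset enumeration (bitmasks)."""
    n = adjacency.shape[0]
    neighbor_mask = [
        sum(1 << j for j in range(n) if adjacency[i, j]) for i in range(n)
    ]
    cliques = []
    for subset in range(1, 1 << n):
        members = [i for i in range(n) if subset >> i & 1]
        if len(members) < min_size:
            continue
        if all(
            subset & ~(1 << i) & ~neighbor_mask[i] == 0 for i in members
        ):
            # subset is a clique; maximal iff no vertex extends it
            extendable = any(
                all(adjacency[v, i] for i in members)
                for v in range(n)
                if v not in members
            )
            if not extendable:
                cliques.append(members)
    return sorted(cliques)


# threshold graph -------------------------------------------------------------

def test_rho_zero_complete_and_above_max_empty():
    rng = np.random.default_rng(0)
    C = random_matrix(rng, 6)
    complete = threshold_graph(C, 0.0)
    assert complete.n_edges == 6 * 5 // 2
    off = C.values[np.triu_indices(6, 1)]
    empty = threshold_graph(C, min(1.0, off.max() + 1e-9))
    assert empty.n_edges == 0


def test_edge_rule_is_inclusive():
    values = np.array([[1.0, 0.5], [0.5, 1.0]])
    graph = threshold_graph(matrix_from_values(values), 0.5)
    assert graph.adjacency[0, 1]


def test_toy_edge_list_by_direct_comparison():
    values = np.array(
        [
            [1.0, 0.8, 0.2, 0.6],
            [0.8, 1.0, 0.5, 0.1],
            [0.2, 0.5, 1.0, 0.9],
            [0.6, 0.1, 0.9, 1.0],
        ]
    )
    graph = threshold_graph(matrix_from_values(values), 0.5)
    edges = {(i, j) for i, j in zip(*np.nonzero(np.triu(graph.adjacency)))}
    assert edges == {(0, 1), (0, 3), (1, 2), (2, 3)}


def test_rho_outside_unit_interval_rejected():
    C = random_matrix(np.random.default_rng(1), 3)
    with pytest.raises(ValidationError):
        threshold_graph(C, 1.5)


# connected components --------------------------------------------------------

def test_component_edge_cases():
    C = matrix_from_values(np.eye(4))
    singletons = connected_components(threshold_graph(C, 0.5))
    assert singletons == [["g0"], ["g1"], ["g2"], ["g3"]]

    complete = matrix_from_values(np.ones((4, 4)))
    assert connected_components(threshold_graph(complete, 0.5)) == [
        ["g0", "g1", "g2", "g3"]
    ]


def test_path_and_isolated_vertices():
    values = np.eye(4)
    values[0, 1] = values[1, 0] = 0.9
    C = matrix_from_values(values)
    comps = connected_components(threshold_graph(C, 0.5))
    assert comps == [["g0", "g1"], ["g2"], ["g3"]]


def test_components_match_brute_force_reachability():
    rng = np.random.default_rng(2)
    for _ in range(30):
        n = int(rng.integers(2, 13))
        C = random_matrix(rng, n)
        rho = float(rng.random())
        graph = threshold_graph(C, rho)
        got = [
            sorted(C.indices(comp).tolist())
            for comp in connected_components(graph)
        ]
        assert sorted(got) == sorted(brute_force_components(graph.adjacency))


# component size curves -------------------------------------------------------

def test_size_census_arithmetic():
    # components of sizes {2, 1, 1}: M = 2, A = 4/3
    values = np.eye(4)
    values[0, 1] = values[1, 0] = 0.9
    curve = component_size_curves(matrix_from_values(values), [0.5])
    assert curve.max_size[0] == 2
    assert curve.avg_size[0] == pytest.approx(4 / 3)
    assert curve.counts[0] == {2: 1, 1: 2}


def test_curve_limits_and_conservation():
    rng = np.random.default_rng(3)
    C = random_matrix(rng, 8)
    grid = np.linspace(0, 1, 21)
    curve = component_size_curves(C, grid)
    # rho = 0 on an all-positive matrix: one giant component
    assert curve.max_size[0] == 8 and curve.avg_size[0] == 8
    # rho = 1 (above max off-diagonal): all singletons
    assert curve.max_size[-1] == 1 and curve.avg_size[-1] == 1
    for census in curve.counts:
        assert sum(k * v for k, v in census.items()) == 8
    assert (np.diff(curve.max_size) <= 0).all()
    assert (np.diff(curve.avg_size) <= 1e-12).all()


def test_empty_rho_grid_rejected():
    with pytest.raises(ValidationError):
        component_size_curves(random_matrix(np.random.default_rng(4), 3), [])


# seed cliques ----------------------------------------------------------------

def test_complete_and_edgeless_designated_graphs():
    complete = matrix_from_values(np.ones((4, 4)))
    assert seed_cliques(complete, 0.5) == [["g0", "g1", "g2", "g3"]]
    edgeless = matrix_from_values(np.eye(4))
    assert seed_cliques(edgeless, 0.5) == []


def test_seed_cliques_match_exhaustive_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(25):
        n = int(rng.integers(3, 9))
        C = random_matrix(rng, n)
        rho = float(rng.random())
        graph = threshold_graph(C, rho)
        expected = [
            [f"g{i}" for i in members]
            for members in brute_force_maximal_cliques(graph.adjacency)
        ]
        assert seed_cliques(C, rho) == sorted(expected)


# clique predicates -----------------------------------------------------------

def test_is_clique_inclusive_boundary():
    values = np.array([[1.0, 0.7], [0.7, 1.0]])
    C = matrix_from_values(values)
    assert is_clique(C, ["g0", "g1"], 0.7)
    assert not is_clique(C, ["g0", "g1"], 0.7 + 1e-9)


def test_clique_min_coexpression():
    values = np.array(
        [[1.0, 0.8, 0.9], [0.8, 1.0, 0.7], [0.9, 0.7, 1.0]]
    )
    C = matrix_from_values(values)
    assert clique_min_coexpression(C, C.gene_ids) == pytest.approx(0.7)
    ident = matrix_from_values(np.ones((3, 3)))
    assert clique_min_coexpression(ident, ident.gene_ids) == 1.0


# clique extension ------------------------------------------------------------

def planted_instance(rng, n=20, planted=6, seed_size=3):
    """Matrix with a planted clique over a weak background (pairs in
    [0.2, 0.6]; margin >= 0.1 by construction). Seed pairs sit in
    [0.78, 0.84], all other planted pairs in [0.85, 0.95], so every planted
    member clears the seed's internal minimum."""
    values = rng.uniform(0.2, 0.6, size=(n, n))
    values = (values + values.T) / 2
    members = rng.choice(n, size=planted, replace=False)
    seed_members = set(members[:seed_size].tolist())
    for a, b in combinations(members, 2):
        if a in seed_members and b in seed_members:
            v = rng.uniform(0.78, 0.84)
        else:
            v = rng.uniform(0.85, 0.95)
        values[a, b] = values[b, a] = v
    np.fill_diagonal(values, 1.0)
    C = matrix_from_values(values)
    seed = [f"g{i}" for i in sorted(members[:seed_size])]
    planted_ids = [f"g{i}" for i in sorted(members)]  # matrix (numeric) order
    return C, seed, planted_ids


def test_extension_stops_when_no_gene_qualifies():
    values = np.array(
        [
            [1.0, 0.9, 0.1],
            [0.9, 1.0, 0.1],
            [0.1, 0.1, 1.0],
        ]
    )
    C = matrix_from_values(values)
    clique = extend_clique(C, ["g0", "g1"])
    assert clique.member_ids == ["g0", "g1"]
    assert clique.rho == pytest.approx(0.9)


def test_extension_adds_single_qualifying_gene():
    values = np.array(
        [
            [1.0, 0.8, 0.85, 0.2],
            [0.8, 1.0, 0.9, 0.2],
            [0.85, 0.9, 1.0, 0.2],
            [0.2, 0.2, 0.2, 1.0],
        ]
    )
    C = matrix_from_values(values)
    clique = extend_clique(C, ["g0", "g1"])
    assert clique.member_ids == ["g0", "g1", "g2"]
    assert is_clique(C, clique.member_ids, clique.rho)


def test_greedy_recovers_planted_clique_with_margin():
    rng = np.random.default_rng(6)
    for _ in range(10):
        C, seed, planted_ids = planted_instance(rng)
        greedy = extend_clique(C, seed, mode="greedy")
        exhaustive = extend_clique(C, seed, mode="exhaustive")
        assert greedy.member_ids == planted_ids
        assert greedy.member_ids == exhaustive.member_ids
        assert is_clique(C, greedy.member_ids, greedy.rho)
        assert set(seed) <= set(greedy.member_ids)


def test_extension_rho_frozen_vs_recomputed():
    rng = np.random.default_rng(7)
    C, seed, _ = planted_instance(rng)
    frozen = extend_clique(C, seed)
    recomputed = extend_clique(C, seed, recompute_rho=True)
    assert frozen.member_ids == recomputed.member_ids
    assert recomputed.rho == pytest.approx(
        clique_min_coexpression(C, frozen.member_ids)
    )
    assert frozen.rho >= recomputed.rho - 1e-12
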