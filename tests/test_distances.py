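import math

import networkx as nx
import numpy as np
import pytest

from netscreen import (
    DistanceMatrix,
    FixtureSpec,
    Interactome,
    MetricSpec,
    all_pairs_shortest_path,
    amspl,
    biased_random_walk_distance,
    communicability_distance,
    compute_distance_matrix,
    generate_graph,
    load_distance_matrix,
    random_walk_distance,
    save_distance_matrix,
)
from netscreen.distances import _walk_visiting
from netscreen.errors import FormatError, ParameterError, ValidationError

from conftest import nodeset


def floyd_warshall_oracle(g: Interactome) -> dict:
    """Naive triple-loop relaxation, independent of the production path."""
    ids = sorted(g.nodes)
    d = {(u, v): (0.0 if u == v else math.inf) for u in ids for v in ids}
    for u, v in g.graph.edges():
        w = g.weight(u, v)
        d[(u, v)] = min(d[(u, v)], w)
        d[(v, u)] = min(d[(v, u)], w)
    for k in ids:
        for i in ids:
            for j in ids:
                if d[(i, k)] + d[(k, j)] < d[(i, j)]:
                    d[(i, j)] = d[(i, k)] + d[(k, j)]
    return d


def walk_distance_oracle(g: Interactome, r: float, beta: float) -> dict:
    """Direct dense linear-algebra restatement used as an independent check."""
    ids = sorted(g.nodes)
    A = nx.to_numpy_array(g.graph, nodelist=ids, weight="weight")
    k = (A > 0).sum(axis=1).astype(float)
    M = A * k[None, :] ** beta
    W = M / M.sum(axis=1, keepdims=True)
    n = len(ids)
    out = {}
    for p in range(n):
        e = np.zeros(n)
        e[p] = 1.0
        pi = r * np.linalg.solve(np.eye(n) - (1 - r) * W.T, e)
        for q in range(n):
            out[(ids[p], ids[q])] = 0.0 if p == q else -math.log(pi[q])
    return out


class TestShortestPath:
    def test_path_graph_hops(self, p5):
        D = all_pairs_shortest_path(p5)
        assert D[("v0", "v4")] == 4.0

    def test_disconnected_pairs_are_inf(self):
        g = Interactome(nx.Graph([("a", "b"), ("c", "d")]))
        D = all_pairs_shortest_path(g)
        assert math.isinf(D[("a", "c")])
        assert D[("a", "b")] == 1.0

    def test_weighted_detour_beats_direct(self, weighted_triangle):
        D = all_pairs_shortest_path(weighted_triangle)
        assert D[("a", "c")] == 2.0

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_floyd_warshall(self, er_factory, seed, weighted):
        g = er_factory(n=25, p=0.12, seed=seed, weighted=weighted)
        D = all_pairs_shortest_path(g)
        oracle = floyd_warshall_oracle(g)
        for (u, v), exp in oracle.items():
            got = D[(u, v)]
            if weighted:
                assert got == pytest.approx(exp, abs=1e-9)
            else:
                assert got == exp

    def test_workers_do_not_change_result(self, er_factory):
        g = er_factory(n=40, p=0.1, seed=5)
        a = all_pairs_shortest_path(g, workers=1)
        b = all_pairs_shortest_path(g, workers=4)
        assert np.array_equal(a.values, b.values)

    def test_adding_edge_never_increases_distance(self, er_factory):
        g = er_factory(n=25, p=0.1, seed=11)
        before = all_pairs_shortest_path(g)
        ids = sorted(g.nodes)
        extra = next(
            (u, v) for i, u in enumerate(ids) for v in ids[i + 1 :] if not g.graph.has_edge(u, v)
        )
        g.graph.add_edge(*extra, weight=1.0)
        after = all_pairs_shortest_path(g)
        assert np.all(after.values <= before.values)


class TestRandomWalk:
    def test_single_edge_closed_form(self, single_edge):
        D = random_walk_distance(single_edge, r=0.5)
        assert D[("a", "b")] == pytest.approx(math.log(3), abs=1e-9)

    def test_diagonal_is_zero(self, er_factory):
        g = er_factory(n=20, p=0.2, seed=1)
        D = random_walk_distance(g, r=0.3)
        assert np.all(np.diagonal(D.values) == 0.0)
        assert not D.symmetric

    def test_visiting_rows_sum_to_one(self, er_factory):
        g = er_factory(n=25, p=0.15, seed=2)
        _, visit = _walk_visiting(g, r=0.15, beta=0.0)
        assert np.allclose(visit.sum(axis=1), 1.0, atol=1e-9)

    def test_cross_component_is_inf(self):
        g = Interactome(nx.Graph([("a", "b"), ("c", "d")]))
        D = random_walk_distance(g)
        assert math.isinf(D[("a", "c")])

    @pytest.mark.parametrize("r", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_restart(self, single_edge, r):
        with pytest.raises(ParameterError):
            random_walk_distance(single_edge, r=r)

    def test_matches_linear_system_oracle(self, er_factory):
        g = er_factory(n=15, p=0.3, seed=4, weighted=True)
        D = random_walk_distance(g, r=0.2)
        oracle = walk_distance_oracle(g, r=0.2, beta=0.0)
        for pair, exp in oracle.items():
            assert D[pair] == pytest.approx(exp, abs=1e-9)


class TestBiasedRandomWalk:
    def test_beta_zero_equals_unbiased(self, er_factory):
        g = er_factory(n=25, p=0.15, seed=3, weighted=True)
        unbiased = random_walk_distance(g, r=0.15)
        biased = biased_random_walk_distance(g, r=0.15, beta=0.0)
        assert np.allclose(biased.values, unbiased.values, atol=1e-12, equal_nan=False)

    def test_star_high_beta_concentrates_on_hub(self, star4):
        D = biased_random_walk_distance(star4, r=0.15, beta=5.0)
        assert D[("l1", "c")] < D[("l1", "l2")]
        oracle = walk_distance_oracle(star4, r=0.15, beta=5.0)
        assert D[("l1", "c")] == pytest.approx(oracle[("l1", "c")], abs=1e-9)
        assert D[("l1", "l2")] == pytest.approx(oracle[("l1", "l2")], abs=1e-9)

    def test_regular_graph_independent_of_beta(self):
        g = Interactome(nx.cycle_graph([f"c{i}" for i in range(8)]))
        a = biased_random_walk_distance(g, r=0.2, beta=0.0)
        b = biased_random_walk_distance(g, r=0.2, beta=2.5)
        assert np.allclose(a.values, b.values, atol=1e-12)


class TestCommunicability:
    def test_single_edge_closed_form(self, single_edge):
        D = communicability_distance(single_edge)
        assert D[("a", "b")] == pytest.approx(math.sqrt(2 / math.e), abs=1e-9)

    def test_diagonal_zero_and_symmetric(self, er_factory):
        g = er_factory(n=20, p=0.2, seed=6)
        D = communicability_distance(g)
        assert np.all(np.diagonal(D.values) == 0.0)
        assert np.array_equal(D.values, D.values.T)

    def test_isomorphic_relabel_preserves_distance_multiset(self, er_factory):
        g = er_factory(n=12, p=0.3, seed=7)
        mapping = {n: f"x{n}" for n in g.nodes}
        h = Interactome(nx.relabel_nodes(g.graph, mapping))
        a = np.sort(communicability_distance(g).values, axis=None)
        b = np.sort(communicability_distance(h).values, axis=None)
        assert np.allclose(a, b, atol=1e-9)

    @pytest.mark.parametrize("metric", ["shortest_path", "communicability"])
    def test_triangle_inequality(self, er_factory, metric):
        g = er_factory(n=15, p=0.35, seed=8)
        D = compute_distance_matrix(g, MetricSpec(kind=metric))
        v = D.values
        n = len(D.ids)
        for k in range(n):
            lhs = v
            rhs = v[:, k][:, None] + v[k, :][None, :]
            assert np.all(lhs <= rhs + 1e-9)


class TestDispatchAndCustom:
    def test_shortest_path_dispatch(self, p5):
        direct = all_pairs_shortest_path(p5)
        via = compute_distance_matrix(p5, MetricSpec(kind="shortest_path"))
        assert np.array_equal(direct.values, via.values)

    def test_custom_constant_accepted(self, p5):
        def const(g):
            n = g.number_of_nodes()
            vals = np.ones((n, n))
            np.fill_diagonal(vals, 0.0)
            return DistanceMatrix(tuple(g.sorted_nodes()), vals, "const", symmetric=True)

        D = compute_distance_matrix(p5, MetricSpec(kind="custom", custom_fn=const))
        assert D[("v0", "v4")] == 1.0

    def test_custom_negative_entry_rejected(self, p5):
        def bad(g):
            n = g.number_of_nodes()
            vals = np.full((n, n), -1.0)
            np.fill_diagonal(vals, 0.0)
            return DistanceMatrix(tuple(g.sorted_nodes()), vals, "bad", symmetric=True)

        with pytest.raises(ValidationError):
            compute_distance_matrix(p5, MetricSpec(kind="custom", custom_fn=bad))

    def test_custom_requires_fn(self):
        with pytest.raises(ParameterError):
            MetricSpec(kind="custom")


class TestCache:
    def test_round_trip_bit_identical(self, tmp_path, er_factory):
        g = er_factory(n=12, p=0.3, seed=9, weighted=True)
        D = random_walk_distance(g, r=0.25)
        path = tmp_path / "d.nmd"
        save_distance_matrix(D, path)
        back = load_distance_matrix(path)
        assert back.ids == D.ids
        assert back.metric_name == D.metric_name
        assert back.symmetric == D.symmetric
        assert back.params == D.params
        assert back.values.tobytes() == D.values.tobytes()

    def test_round_trip_preserves_inf(self, tmp_path):
        g = Interactome(nx.Graph([("a", "b"), ("c", "d")]))
        D = all_pairs_shortest_path(g)
        path = tmp_path / "d.nmd"
        save_distance_matrix(D, path)
        assert math.isinf(load_distance_matrix(path)[("a", "c")])

    def test_truncated_file_is_format_error(self, tmp_path, p5):
        path = tmp_path / "d.nmd"
        save_distance_matrix(all_pairs_shortest_path(p5), path)
        blob = path.read_bytes()
        path.write_bytes(blob[: len(blob) - 16])
        with pytest.raises(FormatError, match="truncated"):
            load_distance_matrix(path)

    def test_bad_magic_is_format_error(self, tmp_path):
        path = tmp_path / "d.nmd"
        path.write_bytes(b"WRONG" + b"\x00" * 64)
        with pytest.raises(FormatError, match="magic"):
            load_distance_matrix(path)

    def test_amspl_identical_after_reload(self, tmp_path, er_factory):
        g = er_factory(n=20, p=0.2, seed=10)
        D = all_pairs_shortest_path(g)
        path = tmp_path / "d.nmd"
        save_distance_matrix(D, path)
        back = load_distance_matrix(path)
        ids = sorted(g.nodes)
        A, B = nodeset(*ids[:4], name="A"), nodeset(*ids[-4:], name="B")
        assert amspl(A, B, back) == amspl(A, B, D)
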