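import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from complexmod import (
    ComplexGraph,
    DegenerateInputError,
    ModularityParams,
    Partition,
    SizeGuardError,
    adjusted_rand_index,
    cluster_best_of,
    exhaustive_best_partition,
    generate_planted_graph,
    iter_set_partitions,
    leiden_once,
    modularity,
    read_partition_tsv,
    write_partition_tsv,
)
from conftest import random_weighted_graph


def modularity_double_sum(g: ComplexGraph, p: Partition, gamma: float = 1.0) -> float:
    """Direct double-sum oracle: (1/2m) sum_ij (A_ij - gamma k_i k_j / 2m) d(c_i, c_j)."""
    m = g.total_weight
    if m == 0:
        return 0.0
    vs = list(g.vertices)
    n = len(vs)
    A = np.zeros((n, n))
    idx = {v: i for i, v in enumerate(vs)}
    for (u, v), w in g.edges.items():
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    k = A.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if p[vs[i]] == p[vs[j]]:
                q += A[i, j] - gamma * k[i] * k[j] / (2 * m)
    return q / (2 * m)


class TestModularity:
    def test_single_module_is_zero(self, barbell_graph):
        p = Partition({v: 0 for v in barbell_graph.vertices})
        assert modularity(barbell_graph, p) == pytest.approx(0.0)

    def test_worked_two_pair_values(self, two_pair_graph):
        pairs = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        singletons = Partition({"a": 0, "b": 1, "c": 2, "d": 3})
        assert modularity(two_pair_graph, pairs) == pytest.approx(0.5)
        assert modularity(two_pair_graph, singletons) == pytest.approx(-0.25)

    def test_edgeless_graph_q_is_zero(self):
        g = ComplexGraph(vertices=("a", "b", "c"), edges={})
        assert modularity(g, Partition({"a": 0, "b": 1, "c": 2})) == 0.0

    def test_partial_partition_rejected(self, two_pair_graph):
        with pytest.raises(ValueError):
            modularity(two_pair_graph, Partition({"a": 0, "b": 0}))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 10),
        gamma=st.floats(0.25, 3.0),
        k=st.integers(1, 4),
    )
    def test_matches_double_sum_definition(self, seed, n, gamma, k):
        rng = np.random.default_rng(seed)
        g = random_weighted_graph(rng, n)
        memb = {v: int(rng.integers(0, k)) for v in g.vertices}
        ids = sorted(set(memb.values()))
        remap = {c: i for i, c in enumerate(ids)}
        p = Partition({v: remap[c] for v, c in memb.items()})
        assert modularity(g, p, gamma) == pytest.approx(modularity_double_sum(g, p, gamma), abs=1e-12)


class TestSetPartitionEnumeration:
    @pytest.mark.parametrize("n,bell", [(1, 1), (2, 2), (3, 5), (4, 15), (5, 52)])
    def test_bell_numbers(self, n, bell):
        items = [str(i) for i in range(n)]
        parts = list(iter_set_partitions(items))
        assert len(parts) == bell
        canon = {tuple(tuple(sorted(b)) for b in sorted(p, key=lambda b: b[0])) for p in parts}
        assert len(canon) == bell  # all distinct


class TestExhaustiveOracle:
    def test_single_edge_pairs_up(self):
        g = ComplexGraph(vertices=("a", "b"), edges={("a", "b"): 1})
        assert exhaustive_best_partition(g).k == 1

    def test_edgeless_returns_singletons(self):
        g = ComplexGraph(vertices=("a", "b", "c"), edges={})
        assert exhaustive_best_partition(g).k == 3

    def test_barbell_optimum_is_two_cliques(self, barbell_graph):
        best = exhaustive_best_partition(barbell_graph)
        assert sorted(map(sorted, best.modules())) == [["a", "b", "c"], ["d", "e", "f"]]
        assert modularity(barbell_graph, best) == pytest.approx(5 / 14)

    def test_size_guard(self):
        labels = tuple(f"v{i:02d}" for i in range(11))
        with pytest.raises(SizeGuardError):
            exhaustive_best_partition(ComplexGraph(vertices=labels, edges={}))


class TestLeidenOnce:
    def test_edgeless_graph_stays_singleton(self):
        g = ComplexGraph(vertices=("a", "b", "c", "d"), edges={})
        p = leiden_once(g, seed=0)
        assert p.k == 4
        assert modularity(g, p) == 0.0

    def test_barbell_recovers_cliques(self, barbell_graph):
        p = leiden_once(barbell_graph, seed=1, audit=True)
        assert modularity(barbell_graph, p) == pytest.approx(5 / 14)

    def test_planted_blocks_recovered(self):
        g, truth = generate_planted_graph(2, 3, w_in=10, w_out=1, p_out=1.0, seed=0)
        p = leiden_once(g, seed=5, audit=True)
        assert adjusted_rand_index(p, truth.membership) == 1.0

    def test_empty_graph_rejected(self):
        with pytest.raises(DegenerateInputError):
            leiden_once(ComplexGraph(vertices=(), edges={}))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 12))
    def test_audit_invariants_hold_on_random_graphs(self, seed, n):
        """Q monotone across iterations; aggregation preserves Q (asserted inside)."""
        g = random_weighted_graph(np.random.default_rng(seed), n)
        leiden_once(g, seed=seed, audit=True)


class TestBestOfProtocol:
    def test_single_run_degenerates_to_leiden_once(self, barbell_graph):
        res = cluster_best_of(barbell_graph, n_runs=1, base_seed=17)
        assert res.best == leiden_once(barbell_graph, seed=17)
        assert res.n_runs == 1

    def test_best_q_is_max_of_runs(self, barbell_graph):
        res = cluster_best_of(barbell_graph, n_runs=25, base_seed=0)
        assert res.best_q == max(res.run_qs)
        assert res.best_q >= max(res.run_qs) - 1e-15

    def test_barbell_attains_enumeration_optimum(self, barbell_graph):
        res = cluster_best_of(barbell_graph, n_runs=200, base_seed=0)
        assert res.best_q == pytest.approx(5 / 14)

    def test_determinism(self):
        g, _ = generate_planted_graph(3, 4, w_in=8, w_out=1, p_out=0.3, seed=2)
        r1 = cluster_best_of(g, n_runs=15, base_seed=99)
        r2 = cluster_best_of(g, n_runs=15, base_seed=99)
        assert r1 == r2

    def test_canonical_module_numbering(self):
        g, _ = generate_planted_graph(2, 3, w_in=10, w_out=1, p_out=0.0, seed=0)
        res = cluster_best_of(g, n_runs=5, base_seed=3)
        # module 0 must contain the smallest vertex label
        first = sorted(res.best.membership)[0]
        assert res.best[first] == 0

    def test_resolution_parameter_controls_granularity(self, barbell_graph):
        coarse = cluster_best_of(barbell_graph, ModularityParams(gamma=0.1), n_runs=30, base_seed=0)
        fine = cluster_best_of(barbell_graph, ModularityParams(gamma=4.0), n_runs=30, base_seed=0)
        assert coarse.best.k <= fine.best.k


class TestAgainstIndependentImplementations:
    """Cross-checks against igraph/leidenalg, never used in the implementation."""

    def test_modularity_matches_igraph(self):
        ig = pytest.importorskip("igraph")
        rng = np.random.default_rng(31)
        for _ in range(20):
            g = random_weighted_graph(rng, int(rng.integers(3, 12)))
            if g.n_edges == 0:
                continue
            memb = {v: int(rng.integers(0, 3)) for v in g.vertices}
            ids = sorted(set(memb.values()))
            remap = {c: i for i, c in enumerate(ids)}
            p = Partition({v: remap[c] for v, c in memb.items()})
            G = ig.Graph()
            G.add_vertices(list(g.vertices))
            G.add_edges(list(g.edges), attributes={"weight": list(g.edges.values())})
            gamma = float(rng.uniform(0.5, 2.0))
            assert modularity(g, p, gamma) == pytest.approx(
                G.modularity([p[v] for v in g.vertices], weights="weight", resolution=gamma),
                abs=1e-10,
            )

    def test_best_q_matches_leidenalg_on_planted_graph(self):
        ig = pytest.importorskip("igraph")
        la = pytest.importorskip("leidenalg")
        g, truth = generate_planted_graph(4, 5, w_in=10, w_out=1, p_out=0.1, seed=7)
        mine = cluster_best_of(g, n_runs=50, base_seed=0)
        G = ig.Graph()
        G.add_vertices(list(g.vertices))
        G.add_edges(list(g.edges), attributes={"weight": list(g.edges.values())})
        best_la = -math.inf
        for s in range(50):
            part = la.find_partition(
                G, la.RBConfigurationVertexPartition, weights="weight",
                resolution_parameter=1.0, n_iterations=-1, seed=s,
            )
            memb = {G.vs[i]["name"]: part.membership[i] for i in range(G.vcount())}
            ids = sorted(set(memb.values()))
            remap = {c: i for i, c in enumerate(ids)}
            best_la = max(best_la, modularity(g, Partition({v: remap[c] for v, c in memb.items()})))
        assert mine.best_q == pytest.approx(best_la, abs=1e-9)
        assert adjusted_rand_index(mine.best, truth.membership) == 1.0


class TestPartitionFile:
    def test_roundtrip(self, tmp_path, barbell_graph):
        res = cluster_best_of(barbell_graph, n_runs=10, base_seed=0)
        path = write_partition_tsv(res.best, tmp_path / "p.tsv", q=res.best_q,
                                   gamma=1.0, n_runs=10, base_seed=0)
        assert read_partition_tsv(path) == res.best
        header = path.read_text().splitlines()[0]
        assert header.startswith("# Q=") and "gamma=1" in header and "runs=10" in header and "seed=0" in header

    def test_identical_bytes_for_identical_inputs(self, tmp_path, barbell_graph):
        res = cluster_best_of(barbell_graph, n_runs=1, base_seed=7)
        p1 = write_partition_tsv(res.best, tmp_path / "a.tsv", q=res.best_q, gamma=1.0, n_runs=1, base_seed=7)
        res2 = cluster_best_of(barbell_graph, n_runs=1, base_seed=7)
        p2 = write_partition_tsv(res2.best, tmp_path / "b.tsv", q=res2.best_q, gamma=1.0, n_runs=1, base_seed=7)
        assert p1.read_bytes() == p2.read_bytes()
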