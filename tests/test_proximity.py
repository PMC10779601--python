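import itertools

import numpy as np
import pytest

from endoprox import (
    DistanceMatrix,
    GeneSet,
    ModuleCatalog,
    build_degree_bins,
    closest_distance,
    proximity_z,
    sample_degree_matched,
    screen_modules,
)
from endoprox.proximity import ScreenTable, _closest_from_matrix, child_seed_sequence

from conftest import brute_closest_distance, make_graph, random_connected_graph


def gs(name, *genes):
    return GeneSet(name, frozenset(genes))


class TestClosestDistance:
    def test_identical_singletons_are_at_zero(self, path5):
        assert closest_distance(path5, gs("a", "3"), gs("b", "3")) == 0.0

    def test_path_endpoints(self, path5):
        assert closest_distance(path5, gs("a", "1"), gs("b", "5")) == 4.0

    def test_two_against_middle(self, path5):
        assert closest_distance(path5, gs("a", "1", "5"), gs("b", "3")) == 2.0

    def test_single_edge(self):
        g = make_graph([("a", "b")])
        assert closest_distance(g, gs("A", "a"), gs("B", "b")) == 1.0

    def test_member_outside_graph_errors(self, path5):
        with pytest.raises(ValueError, match="outside"):
            closest_distance(path5, gs("a", "1", "zz"), gs("b", "5"))

    def test_unreachable_member_errors(self):
        g = make_graph([("a", "b")], nodes=["c"])
        with pytest.raises(ValueError, match="no path"):
            closest_distance(g, gs("A", "a"), gs("B", "c"))

    def test_matches_brute_force_oracle_and_matrix_route(self):
        """BFS route, matrix route and Floyd-Warshall double loop agree."""
        rng = np.random.default_rng(3)
        for _ in range(40):
            g = random_connected_graph(rng)
            nodes = sorted(g.graph.nodes)
            a = rng.choice(nodes, size=int(rng.integers(1, 6)), replace=False)
            b = rng.choice(nodes, size=int(rng.integers(1, 6)), replace=False)
            A, B = gs("A", *a), gs("B", *b)
            expected = brute_closest_distance(g, A.genes, B.genes)
            assert closest_distance(g, A, B) == pytest.approx(expected)
            dm = DistanceMatrix.from_graph(g)
            got = _closest_from_matrix(dm, dm.indices_of(A.genes), dm.indices_of(B.genes))
            assert got == pytest.approx(expected)

    def test_symmetric_and_bounded_by_diameter(self):
        import networkx as nx

        rng = np.random.default_rng(5)
        for _ in range(20):
            g = random_connected_graph(rng, max_nodes=30)
            nodes = sorted(g.graph.nodes)
            a = rng.choice(nodes, size=3, replace=False)
            b = rng.choice(nodes, size=3, replace=False)
            A, B = gs("A", *a), gs("B", *b)
            d_ab = closest_distance(g, A, B)
            assert d_ab == pytest.approx(closest_distance(g, B, A))
            assert 0 <= d_ab <= nx.diameter(g.graph)


class TestDegreeMatchedSampling:
    def test_sample_size_and_distinctness(self, k6):
        bins = build_degree_bins(k6, min_bin_size=2)
        s = sample_degree_matched(k6, bins, gs("t", "a", "b", "c"), rng=0)
        assert len(s) == 3
        assert s <= set("abcdef")

    def test_whole_graph_template_returns_whole_graph(self, k6):
        bins = build_degree_bins(k6, min_bin_size=2)
        s = sample_degree_matched(k6, bins, gs("t", *"abcdef"), rng=0)
        assert s == frozenset("abcdef")

    def test_fixed_seed_repeats(self, k6):
        bins = build_degree_bins(k6, min_bin_size=2)
        a = sample_degree_matched(k6, bins, gs("t", "a", "b"), rng=42)
        b = sample_degree_matched(k6, bins, gs("t", "a", "b"), rng=42)
        assert a == b

    def test_uniform_inclusion_on_regular_graph(self, k6):
        """On a one-bin (regular) graph every node appears with freq ~ k/n."""
        bins = build_degree_bins(k6, min_bin_size=2)
        k, n, n_draws = 2, 6, 10_000
        rng = np.random.default_rng(1)
        counts = {node: 0 for node in "abcdef"}
        for _ in range(n_draws):
            for node in sample_degree_matched(k6, bins, gs("t", "a", "b"), rng):
                counts[node] += 1
        p = k / n
        sigma = np.sqrt(n_draws * p * (1 - p))
        for node, c in counts.items():
            assert abs(c - n_draws * p) < 3 * sigma, (node, c)


def exhaustive_singleton_null(g, a, b, bins, mode="both"):
    """Enumerate the degree-matched null for singleton sets exactly."""
    dm = DistanceMatrix.from_graph(g)
    pool_a = bins.bin_of(a).nodes if mode == "both" else (a,)
    pool_b = bins.bin_of(b).nodes
    ds = []
    for aa, bb in itertools.product(pool_a, pool_b):
        ia = dm.indices_of([aa])
        ib = dm.indices_of([bb])
        ds.append(_closest_from_matrix(dm, ia, ib))
    return np.array(ds)


class TestProximityZ:
    def test_k6_null_mean_matches_exhaustive_five_sixths(self, k6):
        """All K6 nodes share one bin: exhaustive null mean is 5/6."""
        bins = build_degree_bins(k6, min_bin_size=2)
        null = exhaustive_singleton_null(k6, "a", "d", bins)
        assert null.mean() == pytest.approx(5 / 6)
        res = proximity_z(
            k6, gs("A", "a"), gs("B", "d"), n_permutations=10_000, seed=1,
            bins=bins, keep_null=True,
        )
        se = null.std(ddof=0) / np.sqrt(res.n_permutations)
        assert abs(res.null_mean - 5 / 6) < 3 * se

    def test_identical_sets_give_zero_distance_and_add_one_p(self, k6):
        bins = build_degree_bins(k6, min_bin_size=2)
        res = proximity_z(
            k6, gs("A", "a", "b"), gs("B", "a", "b"),
            n_permutations=2000, seed=3, bins=bins, keep_null=True,
        )
        assert res.d_observed == 0.0
        r = int((res.null_distances <= 0.0).sum())
        assert res.p_empirical == (r + 1) / (res.n_permutations + 1)
        assert res.p_empirical > 0

    def test_same_seed_bit_identical(self, k6):
        bins = build_degree_bins(k6, min_bin_size=2)
        kw = dict(n_permutations=500, seed=7, bins=bins)
        r1 = proximity_z(k6, gs("A", "a"), gs("B", "d"), **kw)
        r2 = proximity_z(k6, gs("A", "a"), gs("B", "d"), **kw)
        assert r1.to_dict() == r2.to_dict()

    def test_degenerate_null_flagged_not_infinite(self):
        """Fixed A vs a singleton-bin B gives a constant null: z is NaN."""
        g = make_graph([("a", "b"), ("b", "c")])
        # degree-1 bin {a, c}; degree-2 bin {b}: resampling B={b} is constant
        bins = build_degree_bins(g, min_bin_size=1)
        res = proximity_z(
            g, gs("A", "a"), gs("B", "b"), n_permutations=100, seed=0,
            bins=bins, mode="B-only",
        )
        assert res.degenerate
        assert np.isnan(res.z)
        assert 0 < res.p_empirical <= 1

    def test_empirical_p_never_zero(self, k6):
        bins = build_degree_bins(k6, min_bin_size=2)
        res = proximity_z(
            k6, gs("A", "a"), gs("B", "a"), n_permutations=200, seed=0, bins=bins
        )
        assert res.p_empirical >= 1 / 201

    def test_b_only_mode_keeps_module_fixed(self, path5):
        bins = build_degree_bins(path5, min_bin_size=5)
        res = proximity_z(
            path5, gs("A", "1"), gs("B", "5"),
            n_permutations=300, seed=2, bins=bins, mode="B-only", keep_null=True,
        )
        # with A fixed at an end node and B resampled from the single bin,
        # every null distance equals d('1', b') for some node b'
        dists = {0.0, 1.0, 2.0, 3.0, 4.0}
        assert set(np.unique(res.null_distances)) <= dists

    def test_rejects_bad_mode_and_nperm(self, k6):
        with pytest.raises(ValueError):
            proximity_z(k6, gs("A", "a"), gs("B", "b"), mode="nope")
        with pytest.raises(ValueError):
            proximity_z(k6, gs("A", "a"), gs("B", "b"), n_permutations=0)


class TestScreen:
    def _scenario(self):
        rng = np.random.default_rng(20)
        g = random_connected_graph(rng, max_nodes=40)
        nodes = sorted(g.graph.nodes)
        targets = gs("targets", *rng.choice(nodes, size=5, replace=False))
        catalog = ModuleCatalog(
            modules=[
                GeneSet("near", frozenset(targets.genes), category="c1"),
                GeneSet("far", frozenset(rng.choice(nodes, 4, replace=False)), category="c2"),
                GeneSet("ghost", frozenset({"not_in_graph"}), category="c3"),
            ]
        )
        return g, targets, catalog

    def test_zero_coverage_module_gets_na_row(self):
        g, targets, catalog = self._scenario()
        table = screen_modules(
            g, targets, catalog, n_permutations=200, seed=1, min_bin_size=3
        )
        df = table.to_frame()
        assert set(df["module"]) == {"near", "far", "ghost"}
        ghost = df[df["module"] == "ghost"].iloc[0]
        assert np.isnan(ghost["z"]) and not ghost["significant"]
        # NA rows sort last
        assert df.iloc[-1]["module"] == "ghost"

    def test_catalog_order_does_not_change_results(self):
        g, targets, catalog = self._scenario()
        rev = ModuleCatalog(modules=list(reversed(catalog.modules)))
        kw = dict(n_permutations=300, seed=9, min_bin_size=3)
        t1 = screen_modules(g, targets, catalog, **kw).to_frame()
        t2 = screen_modules(g, targets, rev, **kw).to_frame()
        assert t1.equals(t2)

    def test_child_seed_depends_on_name_only(self):
        s1 = child_seed_sequence(5, "moduleA")
        s2 = child_seed_sequence(5, "moduleA")
        s3 = child_seed_sequence(5, "moduleB")
        assert s1.entropy == s2.entropy != s3.entropy

    @pytest.mark.parametrize(
        "z,p,expected",
        [(-2.0, 0.01, True), (-2.0, 0.20, False), (-1.5, 0.001, False)],
    )
    def test_significance_needs_both_thresholds(self, z, p, expected):
        from endoprox.proximity import ProximityResult

        res = ProximityResult(
            module_name="m", drug_name="d", d_observed=1.0, null_mean=1.5,
            null_sd=0.2, z=z, p_empirical=p, p_normal=p, n_permutations=100,
            seed=0, n_A_used=3, n_B_used=3,
        )
        table = ScreenTable(results=[res], skipped=[])
        assert table.is_significant(res) is expected
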