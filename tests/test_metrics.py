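"""Metric correctness against hand values and brute-force oracles."""

import numpy as np
import pytest

from centrospat import (
    InsufficientPointsError,
    MetricSettings,
    NucleusRegion,
    RadiiGrid,
    SpatialGraph,
    SpotPattern,
    assortativity,
    build_knn_graph,
    compute_all_metrics,
    dispersion_index,
    mnnd,
    modularity_louvain,
    morans_i,
    ripley_clustering_percentage,
    ripley_k,
)
from conftest import random_pattern
from oracles import (
    assortativity_bruteforce,
    clustering_pct_bruteforce,
    dispersion_bruteforce,
    knn_edges_bruteforce,
    mnnd_bruteforce,
    modularity_bruteforce,
    morans_i_bruteforce,
    ripley_k_bruteforce,
)


def pattern_from(xy, radius=50.0, center=(0.0, 0.0)):
    return SpotPattern(NucleusRegion(center=center, radius=radius), np.asarray(xy, float), "test")


def square_region_pattern(xy, area):
    # region whose area property is overridden through an equivalent circle
    r = np.sqrt(area / np.pi)
    return SpotPattern(NucleusRegion(center=(0.0, 0.0), radius=r), np.asarray(xy, float), "test")


class TestRipleyK:
    def test_two_points_step_function(self):
        # A=100, two points 5 apart: K jumps from 0 to A*2/N^2 = 50 at r=5
        p = square_region_pattern([[0, 0], [5, 0]], area=100.0)
        k = ripley_k(p, np.array([0.0, 4.9, 5.0, 10.0]))
        np.testing.assert_allclose(k, [0.0, 0.0, 50.0, 50.0])

    def test_saturation_at_max_distance(self, rng):
        p = random_pattern(rng, 8)
        k = ripley_k(p, np.array([1000.0]))
        np.testing.assert_allclose(k, p.region.area * 7 / 8)

    def test_matches_bruteforce_on_fixed_points(self):
        xy = np.array([[0, 0], [3, 0], [0, 4], [10, 10], [6, 8]], float)
        p = square_region_pattern(xy, area=400.0)
        radii = np.arange(1.0, 16.0)
        np.testing.assert_allclose(
            ripley_k(p, radii), ripley_k_bruteforce(xy, 400.0, radii), atol=1e-12
        )

    def test_monotone_nondecreasing_and_zero_at_origin(self, rng):
        p = random_pattern(rng, 20)
        k = ripley_k(p, RadiiGrid(r_max=20.0))
        assert k[0] == 0.0
        assert (np.diff(k) >= 0).all()

    def test_insufficient_points(self):
        with pytest.raises(InsufficientPointsError):
            ripley_k(pattern_from([[0, 0]]))


class TestClusteringPercentage:
    def test_tight_cluster_saturates(self, rng):
        # all 46 spots within 1 px of the center of a radius-46 nucleus.
        # At r = r_max = R the estimator saturates at A(N-1)/N < pi R^2, so
        # the top step can never count: the ceiling is 100 (n_steps-1)/n_steps.
        region = NucleusRegion(center=(0.0, 0.0), radius=46.0)
        xy = rng.uniform(-0.7, 0.7, (46, 2))
        p = SpotPattern(region, xy, "test")
        assert ripley_clustering_percentage(p) == pytest.approx(98.0)

    def test_single_spot_errors(self):
        with pytest.raises(InsufficientPointsError):
            ripley_clustering_percentage(pattern_from([[0, 0]]))

    def test_range_and_scale_invariance(self, rng):
        p = random_pattern(rng, 30, radius=20.0)
        pct = ripley_clustering_percentage(p, RadiiGrid(r_max=20.0))
        assert 0.0 <= pct <= 100.0
        # scaling coordinates, region and radii together leaves the score fixed
        scaled = SpotPattern(
            NucleusRegion(center=(0.0, 0.0), radius=60.0), p.spots * 3.0, "test"
        )
        assert ripley_clustering_percentage(scaled, RadiiGrid(r_max=60.0)) == pct


class TestKnnGraph:
    def test_degrees_and_weights(self, rng):
        p = random_pattern(rng, 12)
        g = build_knn_graph(p, k=10)
        deg = np.zeros(12)
        for i, j in g.edges:
            deg[i] += 1
            deg[j] += 1
        assert (deg >= 10).all()
        # weight of a 2-px pair is 1/4
        p2 = pattern_from([[0, 0], [2, 0], [9, 9], [12, 0], [0, 12], [20, 20],
                           [25, 0], [0, 25], [30, 30], [40, 0], [0, 40], [40, 40]])
        g2 = build_knn_graph(p2, k=3)
        w = {tuple(e): w for e, w in zip(g2.edges.tolist(), g2.weights)}
        assert w[(0, 1)] == pytest.approx(0.25)

    def test_edge_set_matches_bruteforce(self, rng):
        p = random_pattern(rng, 46)
        g = build_knn_graph(p, k=10)
        edges, weights = knn_edges_bruteforce(p.spots, 10)
        assert {tuple(e) for e in g.edges.tolist()} == edges
        for e, w in zip(g.edges.tolist(), g.weights):
            assert w == pytest.approx(weights[tuple(e)], abs=1e-12)

    def test_too_few_points(self, rng):
        with pytest.raises(InsufficientPointsError):
            build_knn_graph(random_pattern(rng, 8), k=10)


class TestAssortativity:
    def test_star_graph_is_perfectly_disassortative(self):
        # unit-weight K_{1,5}: endpoint degrees are perfectly anti-correlated
        edges = np.array([[0, i] for i in range(1, 6)])
        g = SpatialGraph(6, edges, np.ones(5))
        assert assortativity(g) == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        # 4-cycle with unit weights: every strength equals 2
        edges = np.array([[0, 1], [1, 2], [2, 3], [0, 3]])
        g = SpatialGraph(4, edges, np.ones(4))
        val, flag = assortativity(g, return_flag=True)
        assert val == 0.0 and flag

    def test_csr_assortativity_near_zero(self, nine_configs, rng):
        from centrospat.simulators import sample_pattern

        vals = [
            assortativity(build_knn_graph(sample_pattern(nine_configs["CSR"], rng)))
            for _ in range(100)
        ]
        assert abs(np.mean(vals)) < 0.15


class TestModularity:
    def test_two_cliques_give_half(self):
        # two disconnected unit-weight 5-cliques: Q = 2 (0.5 - 0.25) = 0.5
        edges = []
        for base in (0, 5):
            edges += [[base + i, base + j] for i in range(5) for j in range(i + 1, 5)]
        g = SpatialGraph(10, np.array(edges), np.ones(len(edges)))
        assert modularity_louvain(g, seed=0) == pytest.approx(0.5)

    def test_complete_graph_zero(self):
        edges = [[i, j] for i in range(6) for j in range(i + 1, 6)]
        g = SpatialGraph(6, np.array(edges), np.ones(len(edges)))
        assert modularity_louvain(g, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_q_matches_definition_on_louvain_partition(self, rng):
        p = random_pattern(rng, 15)
        g = build_knn_graph(p, k=4)
        q, membership = modularity_louvain(g, seed=0, return_partition=True)
        assert q == pytest.approx(modularity_bruteforce(p.spots, 4, membership), abs=1e-9)

    def test_small_clusters_score_higher_than_csr(self, nine_configs, rng):
        from centrospat.simulators import sample_pattern

        def mean_q(name):
            return np.mean(
                [
                    modularity_louvain(
                        build_knn_graph(sample_pattern(nine_configs[name], rng))
                    )
                    for _ in range(60)
                ]
            )

        assert mean_q("UTHA") > mean_q("CSR")


class TestMoransI:
    def test_two_points_perfectly_dispersed(self):
        assert morans_i(pattern_from([[1, 1], [3, 5]])) == pytest.approx(-1.0)

    def test_matches_bruteforce_on_fixed_points(self):
        xy = np.array([[0, 0], [0, 1], [10, 10], [10, 11]], float)
        assert morans_i(pattern_from(xy)) == pytest.approx(
            morans_i_bruteforce(xy), abs=1e-12
        )

    def test_adjacent_clusters_beat_central_cluster(self, nine_configs, rng):
        from centrospat.simulators import sample_pattern

        uta = np.mean(
            [morans_i(sample_pattern(nine_configs["UTA"], rng)) for _ in range(60)]
        )
        s2dg = np.mean(
            [morans_i(sample_pattern(nine_configs["S2DG"], rng)) for _ in range(60)]
        )
        assert uta > s2dg


class TestMnndAndDispersion:
    def test_two_points(self):
        assert mnnd(pattern_from([[0, 0], [0, 7]])) == pytest.approx(7.0)

    def test_pds_bound(self, nine_configs, rng):
        from centrospat.simulators import sample_pattern

        p = sample_pattern(nine_configs["PDS"], rng)
        assert mnnd(p) >= 10.0

    def test_mnnd_matches_bruteforce(self, rng):
        p = random_pattern(rng, 5)
        assert mnnd(p) == pytest.approx(mnnd_bruteforce(p.spots), abs=1e-12)

    def test_mnnd_scales_linearly(self, rng):
        p = random_pattern(rng, 12)
        scaled = SpotPattern(p.region, p.spots * 2.5, "test")
        assert mnnd(scaled) == pytest.approx(2.5 * mnnd(p))

    def test_equilateral_triangle_zero_dispersion(self):
        xy = [[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]]
        assert dispersion_index(pattern_from(xy)) == pytest.approx(0.0, abs=1e-12)

    def test_collinear_hand_value(self):
        # distances {1,2,3}: population variance 2/3, mean 2, D = 1/3
        assert dispersion_index(pattern_from([[0, 0], [1, 0], [3, 0]])) == pytest.approx(1 / 3)

    def test_dispersion_needs_three(self):
        with pytest.raises(InsufficientPointsError):
            dispersion_index(pattern_from([[0, 0], [1, 1]]))


class TestComputeAll:
    def test_full_pattern_all_finite(self, csr_pattern):
        v = compute_all_metrics(csr_pattern)
        assert all(x is not None and np.isfinite(x) for x in v.as_dict().values())

    def test_two_spot_pattern_partial(self):
        v = compute_all_metrics(pattern_from([[0, 0], [3, 0]]))
        assert v.mnnd == pytest.approx(3.0)
        assert v.dispersion_index is None
        assert v.modularity is None

    def test_batch_reproducibility(self, nine_configs):
        from centrospat import generate_dataset

        def run():
            pats = generate_dataset(nine_configs["UTA"], 5, seed=7)
            return [compute_all_metrics(p).as_dict() for p in pats]

        assert run() == run()


class TestOracleEquivalence:
    """Random-suite equivalence of all six metrics with the brute force."""

    @pytest.mark.parametrize("case", range(30))
    def test_small_random_patterns(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(5, 11))
        p = random_pattern(rng, n, radius=12.0)
        area = p.region.area
        radii = np.linspace(0, 24, 13)
        np.testing.assert_allclose(
            ripley_k(p, radii), ripley_k_bruteforce(p.spots, area, radii), atol=1e-9
        )
        assert morans_i(p) == pytest.approx(morans_i_bruteforce(p.spots), abs=1e-9)
        assert mnnd(p) == pytest.approx(mnnd_bruteforce(p.spots), abs=1e-9)
        assert dispersion_index(p) == pytest.approx(dispersion_bruteforce(p.spots), abs=1e-9)
        k = min(3, n - 1)
        g = build_knn_graph(p, k=k)
        assert assortativity(g) == pytest.approx(assortativity_bruteforce(p.spots, k), abs=1e-9)
        q, memb = modularity_louvain(g, seed=0, return_partition=True)
        assert q == pytest.approx(modularity_bruteforce(p.spots, k, memb), abs=1e-9)
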