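"""Open-path routing: exactness, heuristic soundness, metric agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_open_path, random_distance_matrix, village_from_local_km
from smcplan.routing import (
    DistanceMatrix,
    InstanceTooLarge,
    RoutingError,
    build_distance_matrix,
    held_karp_path,
    heuristic_path,
    route_distance,
)


def _dm(d, labels=None):
    n = d.shape[0]
    labels = labels or tuple(f"hh{i:04d}" for i in range(n))
    return DistanceMatrix(labels=labels, d=d)


def _linear_dm(n, spacing=1.0):
    xs = np.arange(n) * spacing
    return _dm(np.abs(xs[:, None] - xs[None, :]))


class TestDistanceMatrix:
    def test_metrics_agree_at_one_km(self):
        village = village_from_local_km([(0, 0), (1, 0)], children=[1, 1])
        de = build_distance_matrix(village, "euclidean_local").d[0, 1]
        dh = build_distance_matrix(village, "haversine").d[0, 1]
        assert de == pytest.approx(1.0, rel=1e-3)
        assert dh == pytest.approx(1.0, rel=1e-3)

    def test_metrics_agree_at_village_scale(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(-8, 8, size=(10, 2))  # < 20 km across
        village = village_from_local_km(xy, children=np.ones(10))
        de = build_distance_matrix(village, "euclidean_local").d
        dh = build_distance_matrix(village, "haversine").d
        off = ~np.eye(10, dtype=bool)
        assert np.max(np.abs(de[off] - dh[off]) / dh[off]) < 0.005

    def test_single_household_gives_zero_matrix(self):
        village = village_from_local_km([(0, 0)], children=[1])
        dm = build_distance_matrix(village)
        assert dm.d.shape == (1, 1) and dm.d[0, 0] == 0.0

    def test_duplicate_ids_rejected(self, random_village):
        from smcplan.village import Village

        doubled = Village("dup", list(random_village.households[:1]) * 2)
        with pytest.raises(RoutingError, match="duplicate"):
            build_distance_matrix(doubled)


class TestHeldKarp:
    def test_collinear_points_swept_end_to_end(self):
        itinerary = held_karp_path(_linear_dm(5))
        assert itinerary.total_km == pytest.approx(4.0)
        assert itinerary.order in (
            tuple(f"hh{i:04d}" for i in range(5)),
            tuple(f"hh{i:04d}" for i in reversed(range(5))),
        )
        assert itinerary.exact

    def test_right_triangle_path_skips_hypotenuse(self):
        pts = np.array([(0.0, 0.0), (3.0, 0.0), (0.0, 4.0)])
        diff = pts[:, None] - pts[None, :]
        itinerary = held_karp_path(_dm(np.sqrt((diff**2).sum(axis=2))))
        assert itinerary.total_km == pytest.approx(7.0)

    def test_matches_brute_force_on_seeded_random_instances(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 9))
            d = random_distance_matrix(rng, n)
            expected, _ = brute_force_open_path(d)
            assert held_karp_path(_dm(d)).total_km == pytest.approx(expected)

    def test_open_path_no_longer_than_closed_tour(self):
        import itertools

        rng = np.random.default_rng(77)
        d = random_distance_matrix(rng, 7)
        best_cycle = min(
            sum(d[i, j] for i, j in zip(p, p[1:] + p[:1]))
            for p in map(list, itertools.permutations(range(7)))
        )
        assert held_karp_path(_dm(d)).total_km <= best_cycle + 1e-9

    def test_single_household_is_trivial(self):
        itinerary = held_karp_path(_dm(np.zeros((1, 1))))
        assert itinerary.total_km == 0.0 and len(itinerary.order) == 1

    def test_refuses_instances_above_exact_limit(self):
        d = random_distance_matrix(np.random.default_rng(0), 6)
        with pytest.raises(InstanceTooLarge, match="heuristic_path"):
            held_karp_path(_dm(d), exact_limit=5)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 6))
    def test_exactness_property_against_enumeration(self, seed, n):
        d = random_distance_matrix(np.random.default_rng(seed), n)
        expected, _ = brute_force_open_path(d)
        assert held_karp_path(_dm(d)).total_km == pytest.approx(expected)


class TestHeuristic:
    def test_collinear_points_found_optimal(self):
        itinerary = heuristic_path(_linear_dm(12), seed=0)
        assert itinerary.total_km == pytest.approx(11.0)
        assert not itinerary.exact

    def test_never_beats_exact_and_close_on_average(self):
        ratios = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            n = int(rng.integers(5, 11))
            d = random_distance_matrix(rng, n)
            exact = held_karp_path(_dm(d)).total_km
            heur = heuristic_path(_dm(d), seed=seed).total_km
            assert heur >= exact - 1e-9
            ratios.append(heur / exact if exact > 0 else 1.0)
        assert np.mean(ratios) <= 1.05

    def test_deterministic_given_seed(self):
        d = random_distance_matrix(np.random.default_rng(5), 30)
        a = heuristic_path(_dm(d), seed=9)
        b = heuristic_path(_dm(d), seed=9)
        assert a.order == b.order and a.total_km == b.total_km


class TestRouteDistance:
    def test_reversal_leaves_distance_unchanged(self):
        d = random_distance_matrix(np.random.default_rng(2), 8)
        dm = _dm(d)
        order = list(dm.labels)
        assert route_distance(order, dm) == pytest.approx(
            route_distance(order[::-1], dm)
        )

    def test_two_households(self):
        d = np.array([[0.0, 2.5], [2.5, 0.0]])
        dm = _dm(d)
        assert route_distance(dm.labels, dm) == pytest.approx(2.5)

    def test_tracked_order_never_beats_optimized(self):
        rng = np.random.default_rng(8)
        d = random_distance_matrix(rng, 9)
        dm = _dm(d)
        optimal = held_karp_path(dm).total_km
        tracked = list(np.array(dm.labels)[rng.permutation(9)])
        assert route_distance(tracked, dm) >= optimal - 1e-9

    def test_non_permutation_rejected(self):
        dm = _dm(np.zeros((2, 2)))
        with pytest.raises(RoutingError, match="permutation"):
            route_distance([dm.labels[0], dm.labels[0]], dm)
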