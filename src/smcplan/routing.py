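"""Open-path traveling-salesman routing over household locations.

Door-to-door delivery teams visit every household exactly once but do not
return to the start, so the objective is the open-path TSP: over all
orderings (n_1, ..., n_N) minimise the sum of consecutive household
distances, with both endpoints free.

Two solvers are provided:

* :func:`held_karp_path` — exact dynamic programming over vertex subsets,
  O(2^N) states; feasible for small instances (default limit N = 15);
* :func:`heuristic_path` — multi-start nearest-neighbour construction
  followed by 2-opt improvement, for larger villages. Never better than
  the exact optimum, and within a few percent of it on village-scale
  point sets.

Distances are great-circle (haversine) or Euclidean in a local
equirectangular frame centred on the village; at village scale (< 20 km)
the two agree to well under 1%.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from ._geo import haversine_km_matrix, local_km_from_lonlat
from .village import Village

__all__ = [
    "DistanceMatrix",
    "Itinerary",
    "build_distance_matrix",
    "held_karp_path",
    "heuristic_path",
    "route_distance",
]

#: Largest instance the exact solver accepts by default (2^N DP states).
DEFAULT_EXACT_LIMIT = 15

METRICS = ("euclidean_local", "haversine")


class RoutingError(ValueError):
    pass


class InstanceTooLarge(RoutingError):
    """The exact solver was asked for more vertices than its subset DP allows."""


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise household distances in km."""

    labels: tuple[str, ...]
    d: np.ndarray
    metric: str = "euclidean_local"

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise RoutingError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(d)) or (d < 0).any():
            raise RoutingError("distances must be finite and non-negative")
        if not np.allclose(d, d.T):
            raise RoutingError("distance matrix must be symmetric")
        if not np.allclose(np.diagonal(d), 0.0):
            raise RoutingError("distance matrix diagonal must be zero")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclasses.dataclass(frozen=True)
class Itinerary:
    """An ordered visit path over households.

    ``exact`` is True when the order was produced by the exact subset DP
    and therefore carries an optimality guarantee.
    """

    order: tuple[str, ...]
    total_km: float
    exact: bool


def build_distance_matrix(
    village: Village, metric: str = "euclidean_local"
) -> DistanceMatrix:
    """Pairwise km distances between the households of ``village``.

    ``euclidean_local`` projects lon/lat to a metric frame centred on the
    village centroid (equirectangular) before applying the plane formula;
    ``haversine`` uses great-circle distances directly.
    """
    if metric not in METRICS:
        raise RoutingError(f"metric must be one of {METRICS}, got {metric!r}")
    if village.n_households == 0:
        raise RoutingError("cannot build a distance matrix for an empty village")
    labels = village.ids
    if len(set(labels)) != len(labels):
        raise RoutingError("duplicate household ids in village")
    lonlat = village.lonlat
    if metric == "haversine":
        d = haversine_km_matrix(lonlat[:, 0], lonlat[:, 1])
    else:
        x, y = local_km_from_lonlat(
            lonlat[:, 0],
            lonlat[:, 1],
            float(lonlat[:, 0].mean()),
            float(lonlat[:, 1].mean()),
        )
        pts = np.column_stack([x, y])
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, d=d, metric=metric)


def route_distance(order: Sequence[str], dm: DistanceMatrix) -> float:
    """Total length (km) of visiting ``order``; 0 for a single household."""
    if sorted(order) != sorted(dm.labels):
        raise RoutingError("order is not a permutation of the matrix labels")
    index = {label: i for i, label in enumerate(dm.labels)}
    idx = [index[label] for label in order]
    return float(sum(dm.d[i, j] for i, j in zip(idx[:-1], idx[1:])))


def _canonical(order: list[int]) -> list[int]:
    """Pick the lexicographically smaller of a path and its reverse."""
    rev = order[::-1]
    return order if order <= rev else rev


def held_karp_path(
    dm: DistanceMatrix, exact_limit: int = DEFAULT_EXACT_LIMIT
) -> Itinerary:
    """Provably shortest open path by subset dynamic programming.

    The DP computes, for every subset S of households and every j in S, the
    shortest path that visits exactly S and ends at j, with the start free;
    the optimum is the minimum over j of the full-set entries, i.e. the
    minimum over all endpoint pairs. The visit order is recovered by
    backtracking through the table; among equal-cost predecessors the
    smallest index is taken, and the final path is reported in the
    lexicographically smaller of its two traversal directions.
    """
    n = dm.n
    if n > exact_limit:
        raise InstanceTooLarge(
            f"{n} households exceeds the exact limit ({exact_limit}); "
            "use heuristic_path for larger instances"
        )
    if n == 1:
        return Itinerary(order=dm.labels, total_km=0.0, exact=True)
    d = dm.d
    full = (1 << n) - 1
    # cost[mask, j]: shortest path visiting the set `mask`, ending at j
    cost = np.full((full + 1, n), np.inf)
    for j in range(n):
        cost[1 << j, j] = 0.0
    for mask in range(1, full + 1):
        if mask & (mask - 1) == 0:  # singletons already seeded
            continue
        members = [j for j in range(n) if mask >> j & 1]
        for j in members:
            prev = mask ^ (1 << j)
            cost[mask, j] = np.min(cost[prev, members] + d[members, j])
    end = int(np.argmin(cost[full]))
    total = float(cost[full, end])
    # backtrack: n_{k-1} is the (smallest-index) vertex satisfying the
    # optimal-substructure identity at each step
    order = [end]
    mask = full
    while mask & (mask - 1):
        j = order[-1]
        prev = mask ^ (1 << j)
        candidates = [i for i in range(n) if prev >> i & 1]
        costs = cost[prev, candidates] + d[candidates, j]
        order.append(candidates[int(np.argmin(costs))])
        mask = prev
    order.reverse()
    labels = [dm.labels[i] for i in _canonical(order)]
    return Itinerary(order=tuple(labels), total_km=total, exact=True)


def _nearest_neighbour(d: np.ndarray, start: int) -> list[int]:
    n = d.shape[0]
    unvisited = np.ones(n, dtype=bool)
    unvisited[start] = False
    order = [start]
    for _ in range(n - 1):
        here = order[-1]
        dist = np.where(unvisited, d[here], np.inf)
        nxt = int(np.argmin(dist))
        order.append(nxt)
        unvisited[nxt] = False
    return order


def _two_opt(order: list[int], d: np.ndarray) -> list[int]:
    """First-improvement 2-opt for an open path (segment reversal)."""
    n = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            a = order[i - 1] if i > 0 else -1
            for j in range(i + 1, n):
                b = order[j + 1] if j + 1 < n else -1
                before = (d[a, order[i]] if a >= 0 else 0.0) + (
                    d[order[j], b] if b >= 0 else 0.0
                )
                after = (d[a, order[j]] if a >= 0 else 0.0) + (
                    d[order[i], b] if b >= 0 else 0.0
                )
                if after < before - 1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
    return order


def heuristic_path(
    dm: DistanceMatrix, seed: int = 0, n_starts: int = 8
) -> Itinerary:
    """Multi-start nearest-neighbour + 2-opt open path (``exact=False``).

    Deterministic given ``seed``: the seed picks which households serve as
    nearest-neighbour starting points (all of them when N <= n_starts).
    """
    n = dm.n
    if n < 2:
        if n == 1:
            return Itinerary(order=dm.labels, total_km=0.0, exact=False)
        raise RoutingError("heuristic_path needs at least 2 households")
    d = dm.d
    rng = np.random.default_rng(seed)
    if n <= n_starts:
        starts = list(range(n))
    else:
        starts = sorted(rng.choice(n, size=n_starts, replace=False).tolist())
    best_order: list[int] | None = None
    best_cost = np.inf
    for start in starts:
        order = _two_opt(_nearest_neighbour(d, start), d)
        cost = float(sum(d[i, j] for i, j in zip(order[:-1], order[1:])))
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12
            and best_order is not None
            and _canonical(order) < _canonical(best_order)
        ):
            best_order, best_cost = order, cost
    assert best_order is not None
    labels = [dm.labels[i] for i in _canonical(best_order)]
    return Itinerary(order=tuple(labels), total_km=best_cost, exact=False)
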