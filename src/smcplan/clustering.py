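"""Minimum-size-constrained K-means for subdividing hard-to-reach villages.

Villages split by rivers or other barriers are partitioned into k clusters
before routing, so that each cluster gets its own itinerary and CHW team.
Plain K-means can starve a cluster; the constrained variant demands that
cluster h receive at least tau_h points. With centres fixed, the
assignment step is the linear program

    min sum_i sum_h T_ih * (1/2) ||x_i - C_h||^2
    s.t. sum_h T_ih = 1,  sum_i T_ih >= tau_h,  T_ih >= 0,

whose constraint structure is a transportation / minimum-cost-flow problem:
every basic optimum is integral, so the relaxation already yields hard
labels. The solver here routes one unit of flow per point to cluster nodes
with demand tau_h, excess flowing to a zero-cost sink, and alternates this
assignment with the usual centroid update (a cluster left empty keeps its
centre) until centres stop moving.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from ._geo import local_km_from_lonlat
from .village import Village

__all__ = [
    "ClusterPlan",
    "constrained_kmeans",
    "solve_assignment",
    "solve_assignment_lp",
]

#: Integer scale applied to squared-distance costs for the network simplex.
_COST_SCALE = 10**8


class ClusteringError(ValueError):
    pass


class InfeasibleConstraints(ClusteringError):
    """The minimum-size demands exceed the number of points."""


@dataclasses.dataclass(frozen=True)
class ClusterPlan:
    """Result of a constrained K-means run."""

    k: int
    centers: np.ndarray  # (k, 2), same coordinate frame as the input points
    assignment: np.ndarray  # (m,) hard labels in [0, k)
    tau: tuple[int, ...]
    objective: float  # sum of (1/2)||x_i - C_{label_i}||^2 at convergence
    n_iterations: int

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)

    def indices(self, h: int) -> np.ndarray:
        return np.nonzero(self.assignment == h)[0]


def _check_tau(tau: Sequence[int], k: int, m: int) -> tuple[int, ...]:
    tau = tuple(int(t) for t in tau)
    if len(tau) != k:
        raise ClusteringError(f"tau has {len(tau)} entries for k={k} clusters")
    if any(t < 0 for t in tau):
        raise ClusteringError("tau entries must be >= 0")
    if sum(tau) > m:
        raise InfeasibleConstraints(
            f"sum(tau)={sum(tau)} exceeds the number of points m={m}"
        )
    return tau


def _half_sq_cost(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - centers[None, :, :]
    return 0.5 * (diff**2).sum(axis=2)


def solve_assignment(
    points: np.ndarray, centers: np.ndarray, tau: Sequence[int]
) -> np.ndarray:
    """Optimal hard assignment of points to centers under size minima.

    Solved as a minimum-cost flow: each point ships one unit, cluster h
    absorbs tau_h units as demand, and a sink absorbs the remainder at zero
    extra cost. Costs are the halved squared Euclidean distances, scaled to
    integers for the network simplex. Ties resolve to the lowest cluster
    index through the deterministic node ordering.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    m, k = len(points), len(centers)
    tau = _check_tau(tau, k, m)
    cost = _half_sq_cost(points, centers)
    if sum(tau) == 0 or all(t == 0 for t in tau):
        return np.argmin(cost, axis=1)
    scale = _COST_SCALE / max(cost.max(), 1e-300)
    icost = np.rint(cost * scale).astype(np.int64)
    g = nx.DiGraph()
    slack = m - sum(tau)
    for i in range(m):
        g.add_node(("p", i), demand=-1)
    for h in range(k):
        g.add_node(("c", h), demand=tau[h])
    g.add_node("sink", demand=slack)
    for i in range(m):
        for h in range(k):
            g.add_edge(("p", i), ("c", h), weight=int(icost[i, h]), capacity=1)
    for h in range(k):
        g.add_edge(("c", h), "sink", weight=0, capacity=m - tau[h])
    _, flow = nx.network_simplex(g)
    labels = np.empty(m, dtype=int)
    for i in range(m):
        sent = flow[("p", i)]
        chosen = [h for h in range(k) if sent.get(("c", h), 0) > 0]
        labels[i] = min(chosen)
    return labels


def solve_assignment_lp(
    points: np.ndarray, centers: np.ndarray, tau: Sequence[int]
) -> tuple[np.ndarray, float]:
    """Assignment step solved directly as the linear program.

    Returns hard labels (argmax of each point's row, ties to the lowest
    index) and the LP optimum. Used as an independent route to the same
    optimum as the flow formulation; the transportation structure makes
    basic optima integral.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    m, k = len(points), len(centers)
    tau = _check_tau(tau, k, m)
    cost = _half_sq_cost(points, centers).ravel()  # var order: (i, h)
    a_eq = np.zeros((m, m * k))
    for i in range(m):
        a_eq[i, i * k : (i + 1) * k] = 1.0
    a_ub = np.zeros((k, m * k))  # -sum_i T_ih <= -tau_h
    for h in range(k):
        a_ub[h, h::k] = -1.0
    res = linprog(
        cost,
        A_eq=a_eq,
        b_eq=np.ones(m),
        A_ub=a_ub,
        b_ub=-np.asarray(tau, dtype=float),
        bounds=(0, None),
        method="highs",
    )
    if not res.success:
        raise InfeasibleConstraints(res.message)
    t = res.x.reshape(m, k)
    labels = np.array([int(np.argmax(np.isclose(row, row.max()))) for row in t])
    return labels, float(res.fun)


def _kmeans_pp_init(
    points: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Seeded k-means++ centre initialisation."""
    m = len(points)
    centers = np.empty((k, points.shape[1]))
    centers[0] = points[rng.integers(m)]
    d2 = ((points - centers[0]) ** 2).sum(axis=1)
    for h in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[h] = points[rng.integers(m)]
        else:
            centers[h] = points[rng.choice(m, p=d2 / total)]
        d2 = np.minimum(d2, ((points - centers[h]) ** 2).sum(axis=1))
    return centers


def _objective(points: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(0.5 * ((points - centers[labels]) ** 2).sum())


def constrained_kmeans(
    village_or_points: Village | np.ndarray,
    k: int,
    tau: Sequence[int] | None = None,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterPlan:
    """Iterate constrained assignment and centroid update to convergence.

    Accepts a :class:`~smcplan.village.Village` (households are projected
    to a local km frame, so ``tol`` is in km) or a raw (m, n) point array.
    ``tau`` defaults to ``floor(0.8 * m / k)`` per cluster — clusters of
    roughly equal size with 20% slack. The objective is non-increasing
    across iterations and the run is deterministic given ``seed``.
    """
    if isinstance(village_or_points, Village):
        lonlat = village_or_points.lonlat
        if len(lonlat) == 0:
            raise ClusteringError("cannot cluster an empty village")
        x, y = local_km_from_lonlat(
            lonlat[:, 0],
            lonlat[:, 1],
            float(lonlat[:, 0].mean()),
            float(lonlat[:, 1].mean()),
        )
        points = np.column_stack([x, y])
    else:
        points = np.atleast_2d(np.asarray(village_or_points, dtype=float))
    m = len(points)
    if not 1 <= k <= m:
        raise ClusteringError(f"k must satisfy 1 <= k <= m={m}, got {k}")
    if tau is None:
        tau = [int(0.8 * m / k)] * k
    tau = _check_tau(tau, k, m)
    rng = np.random.default_rng(seed)
    centers = _kmeans_pp_init(points, k, rng)
    labels = solve_assignment(points, centers, tau)
    iteration = 0
    for iteration in range(1, max_iter + 1):
        new_centers = centers.copy()
        for h in range(k):
            mask = labels == h
            if mask.any():  # an empty cluster keeps its centre
                new_centers[h] = points[mask].mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        labels = solve_assignment(points, centers, tau)
        if shift < tol:
            break
    return ClusterPlan(
        k=k,
        centers=centers,
        assignment=labels,
        tau=tau,
        objective=_objective(points, centers, labels),
        n_iterations=iteration,
    )
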