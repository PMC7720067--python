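"""Shared fixtures and independent brute-force oracles.

The oracles here (exhaustive open-path enumeration, exhaustive constrained
partition enumeration) are deliberately naive and independent of the
package's solvers; they define ground truth on tiny instances.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from smcplan.village import Household, Village, VillageSpec, generate_village


def brute_force_open_path(d: np.ndarray) -> tuple[float, tuple[int, ...]]:
    """Exhaustive minimum open-path cost over all orderings (reverse-deduped)."""
    n = d.shape[0]
    best_cost, best_order = np.inf, None
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:  # a path and its reverse have equal length
            continue
        cost = sum(d[i, j] for i, j in zip(perm[:-1], perm[1:]))
        if cost < best_cost:
            best_cost, best_order = cost, perm
    return float(best_cost), best_order


def brute_force_assignment(
    points: np.ndarray, centers: np.ndarray, tau
) -> float:
    """Exhaustive minimum assignment cost over all label vectors meeting tau."""
    m, k = len(points), len(centers)
    diff = points[:, None, :] - centers[None, :, :]
    cost = 0.5 * (diff**2).sum(axis=2)
    best = np.inf
    for labels in itertools.product(range(k), repeat=m):
        sizes = np.bincount(labels, minlength=k)
        if np.all(sizes >= np.asarray(tau)):
            best = min(best, float(cost[np.arange(m), labels].sum()))
    return best


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric Euclidean distance matrix of n random planar points."""
    pts = rng.uniform(0.0, 10.0, size=(n, 2))
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return (d + d.T) / 2.0


def village_from_local_km(xy, children, name="fixture", family_size=None):
    """Build a village at given local-km offsets around the default origin."""
    from smcplan._geo import lonlat_from_local_km
    from smcplan.village import DEFAULT_ORIGIN

    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    lon, lat = lonlat_from_local_km(xy[:, 0], xy[:, 1], *DEFAULT_ORIGIN)
    households = []
    for i in range(len(xy)):
        kids = int(children[i])
        size = int(family_size[i]) if family_size is not None else max(kids, 1) + 2
        households.append(
            Household(f"hh{i:04d}", float(lon[i]), float(lat[i]), size, kids)
        )
    return Village(name, households)


@pytest.fixture(scope="session")
def random_village():
    """A mid-size random-dispersion village reused across modules."""
    return generate_village(
        VillageSpec(name="mogdin-like", n_households=40, dispersion="random", seed=11)
    )


@pytest.fixture(scope="session")
def line_village():
    """4 collinear households 1 km apart, 1 child each (hand-checkable)."""
    xy = [(i * 1.0, 0.0) for i in range(4)]
    return village_from_local_km(xy, children=[1, 1, 1, 1], name="line")
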