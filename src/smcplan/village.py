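"""Household/village containers and the synthetic-village generator.

A village is the unit of door-to-door campaign planning: an ordered table of
households, each with WGS84 coordinates, a family size and a number of
under-5 children (the SMC-eligible population).

The generator emulates the three settlement-dispersion regimes seen in
rural Burkinabe villages:

``uniform``
    evenly spaced dwellings (jittered grid) — compact, well-mixed villages;
``random``
    homogeneous-Poisson placement — uneven spacing, longer connecting legs;
``clumped``
    households drawn around a few well-separated hamlet centres, the
    pattern produced when water streams or other barriers partition a
    village into hard-to-reach pockets.

Family sizes follow a zero-truncated Poisson law (households are never
empty), and under-5 children are allocated so that the village total equals
the demographic expectation — by default 18% of the population, the
under-5 share typical of Sahelian countries — using a largest-remainder
rule so every household gets an integer count bounded by its family size.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np

from ._geo import lonlat_from_local_km

__all__ = [
    "Household",
    "Village",
    "VillageSpec",
    "allocate_under5",
    "generate_village",
]

#: Default anchor for the synthetic local->WGS84 mapping: Nanoro, Burkina Faso.
DEFAULT_ORIGIN = (-2.19, 12.69)

DISPERSIONS = ("uniform", "random", "clumped")


class VillageValidationError(ValueError):
    """A village specification or household table violates an invariant."""


@dataclasses.dataclass(frozen=True)
class Household:
    """One dwelling: location, family size and number of under-5 children."""

    household_id: str
    lon: float
    lat: float
    family_size: int
    n_under5: int

    def __post_init__(self) -> None:
        if self.family_size < 1:
            raise VillageValidationError(
                f"household {self.household_id!r}: family_size must be >= 1, "
                f"got {self.family_size}"
            )
        if not 0 <= self.n_under5 <= self.family_size:
            raise VillageValidationError(
                f"household {self.household_id!r}: n_under5 must lie in "
                f"[0, family_size], got {self.n_under5}"
            )


@dataclasses.dataclass(frozen=True)
class Village:
    """An ordered collection of households."""

    name: str
    households: tuple[Household, ...]

    def __init__(self, name: str, households: Iterable[Household]) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "households", tuple(households))

    @property
    def n_households(self) -> int:
        return len(self.households)

    @property
    def total_population(self) -> int:
        return sum(h.family_size for h in self.households)

    @property
    def total_children(self) -> int:
        """N in the coverage formulas: all under-5 children in the village."""
        return sum(h.n_under5 for h in self.households)

    @property
    def lonlat(self) -> np.ndarray:
        """(n, 2) array of household (lon, lat)."""
        return np.array([(h.lon, h.lat) for h in self.households], dtype=float).reshape(
            -1, 2
        )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(h.household_id for h in self.households)

    def subset(self, indices: Sequence[int], name: str | None = None) -> "Village":
        return Village(
            name if name is not None else self.name,
            (self.households[i] for i in indices),
        )


@dataclasses.dataclass(frozen=True)
class VillageSpec:
    """Parameters of a synthetic village.

    Parameters
    ----------
    name
        Village label.
    n_households
        Number of dwellings to place.
    dispersion
        ``"uniform"``, ``"random"`` or ``"clumped"``.
    n_clumps
        Number of hamlet centres when ``dispersion == "clumped"``.
    extent_km
        Side length of the square village footprint.
    mean_family_size
        Mean of the zero-truncated Poisson family-size law.
    under5_fraction
        Share of the population aged under 5 (default 0.18).
    seed
        Seed for all randomness in the generator.
    origin
        (lon, lat) anchor at which the local km frame is pinned to WGS84.
    """

    name: str = "synthetic"
    n_households: int = 100
    dispersion: str = "random"
    n_clumps: int = 3
    extent_km: float = 2.0
    mean_family_size: float = 6.0
    under5_fraction: float = 0.18
    seed: int = 0
    origin: tuple[float, float] = DEFAULT_ORIGIN

    def validate(self) -> None:
        if self.n_households < 1:
            raise VillageValidationError(
                f"n_households must be >= 1, got {self.n_households}"
            )
        if self.dispersion not in DISPERSIONS:
            raise VillageValidationError(
                f"dispersion must be one of {DISPERSIONS}, got {self.dispersion!r}"
            )
        if self.extent_km <= 0:
            raise VillageValidationError(
                f"extent_km must be > 0, got {self.extent_km}"
            )
        if not 0 < self.under5_fraction < 1:
            raise VillageValidationError(
                f"under5_fraction must lie in (0, 1), got {self.under5_fraction}"
            )
        if self.mean_family_size < 1:
            raise VillageValidationError(
                f"mean_family_size must be >= 1, got {self.mean_family_size}"
            )
        if self.dispersion == "clumped" and self.n_clumps < 2:
            raise VillageValidationError(
                f"n_clumps must be >= 2 for clumped dispersion, got {self.n_clumps}"
            )


def allocate_under5(
    family_sizes: Sequence[int], under5_fraction: float
) -> np.ndarray:
    """Integer under-5 counts per household via largest-remainder rounding.

    The expected count per household is ``under5_fraction * family_size``;
    quotas are floored and the leftover children (so that the village total
    equals ``round(under5_fraction * total_population)``) are handed to the
    households with the largest fractional remainders, never exceeding a
    household's family size. Ties are broken by household order, which makes
    the allocation deterministic.
    """
    sizes = np.asarray(family_sizes, dtype=int)
    if (sizes < 1).any():
        raise VillageValidationError("family sizes must all be >= 1")
    expected = under5_fraction * sizes
    target = int(round(under5_fraction * int(sizes.sum())))
    base = np.floor(expected).astype(int)
    base = np.minimum(base, sizes)
    remainder = expected - base
    # households already at capacity cannot take extra children
    remainder[base >= sizes] = -1.0
    short = target - int(base.sum())
    while short > 0:
        order = np.argsort(-remainder, kind="stable")
        take = order[: min(short, int((remainder >= 0).sum()))]
        if take.size == 0:  # every household saturated
            break
        base[take] += 1
        remainder[take] -= 1.0
        remainder[base >= sizes] = -1.0
        short = target - int(base.sum())
    return base


def _place_uniform(rng: np.random.Generator, n: int, extent: float) -> np.ndarray:
    """Jittered grid: near-constant nearest-neighbour spacing.

    The first n cells of a ceil(sqrt(n))-sided grid are filled row-major
    (deterministically, so only the jitter varies between seeds) and each
    dwelling is jittered by up to a fifth of the cell size.
    """
    side = int(np.ceil(np.sqrt(n)))
    cell = extent / side
    ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    centers = np.column_stack(
        [(ii.ravel() + 0.5) * cell, (jj.ravel() + 0.5) * cell]
    )[:n]
    jitter = rng.uniform(-cell / 5.0, cell / 5.0, size=(n, 2))
    return centers + jitter


def _place_random(rng: np.random.Generator, n: int, extent: float) -> np.ndarray:
    """Homogeneous (binomial/Poisson-like) placement over the footprint."""
    return rng.uniform(0.0, extent, size=(n, 2))


def _place_clumped(
    rng: np.random.Generator, n: int, extent: float, n_clumps: int
) -> np.ndarray:
    """Gaussian hamlets around well-separated centres.

    Centres are drawn in the inner 80% of the footprint with a minimum
    mutual separation of 0.35 x extent / sqrt(n_clumps) (rejection sampling,
    falling back to the best draw after 200 attempts); each household joins
    a uniformly chosen hamlet with isotropic spread 0.04 x extent.
    """
    min_sep = 0.35 * extent / np.sqrt(n_clumps)
    lo, hi = 0.1 * extent, 0.9 * extent
    centers = np.empty((n_clumps, 2))
    for c in range(n_clumps):
        best, best_d = None, -1.0
        for _ in range(200):
            cand = rng.uniform(lo, hi, size=2)
            d = (
                np.inf
                if c == 0
                else float(np.min(np.hypot(*(centers[:c] - cand).T)))
            )
            if d >= min_sep:
                best = cand
                break
            if d > best_d:
                best, best_d = cand, d
        centers[c] = best
    labels = rng.integers(0, n_clumps, size=n)
    spread = 0.04 * extent
    pts = centers[labels] + rng.normal(0.0, spread, size=(n, 2))
    return np.clip(pts, 0.0, extent)


def _truncated_poisson(
    rng: np.random.Generator, mean: float, size: int
) -> np.ndarray:
    """Poisson(mean) conditioned on being >= 1 (households are not empty)."""
    out = rng.poisson(mean, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(mean, size=int(zero.sum()))
        zero = out == 0
    return out


def generate_village(spec: VillageSpec) -> Village:
    """Generate a synthetic village from ``spec``.

    Deterministic: the same spec (including seed) always yields an
    identical household table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, extent = spec.n_households, spec.extent_km
    if spec.dispersion == "uniform":
        xy = _place_uniform(rng, n, extent)
    elif spec.dispersion == "random":
        xy = _place_random(rng, n, extent)
    else:
        xy = _place_clumped(rng, n, extent, spec.n_clumps)
    # centre the footprint on the origin so the anchor is the village centroid
    xy = xy - extent / 2.0
    family_sizes = _truncated_poisson(rng, spec.mean_family_size, n)
    under5 = allocate_under5(family_sizes, spec.under5_fraction)
    lon, lat = lonlat_from_local_km(xy[:, 0], xy[:, 1], *spec.origin)
    width = max(4, len(str(n)))
    households = [
        Household(
            household_id=f"hh{i:0{width}d}",
            lon=float(lon[i]),
            lat=float(lat[i]),
            family_size=int(family_sizes[i]),
            n_under5=int(under5[i]),
        )
        for i in range(n)
    ]
    return Village(spec.name, households)
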