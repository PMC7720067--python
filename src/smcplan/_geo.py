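"""Small geodesy helpers shared by the village generator and the router.

Villages span a few km, so a local equirectangular frame centred on the
village is metrically indistinguishable (<1%) from proper geodesics; both
that frame and haversine great-circle distances are provided so callers can
pick either and cross-check.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

# km per degree of latitude (spherical Earth)
KM_PER_DEG_LAT = EARTH_RADIUS_KM * np.pi / 180.0


def lonlat_from_local_km(
    x_km: np.ndarray, y_km: np.ndarray, origin_lon: float, origin_lat: float
) -> tuple[np.ndarray, np.ndarray]:
    """Map local metric offsets (km east, km north) to WGS84 lon/lat."""
    lat = origin_lat + np.asarray(y_km) / KM_PER_DEG_LAT
    lon = origin_lon + np.asarray(x_km) / (
        KM_PER_DEG_LAT * np.cos(np.radians(origin_lat))
    )
    return lon, lat


def local_km_from_lonlat(
    lon: np.ndarray, lat: np.ndarray, origin_lon: float, origin_lat: float
) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to km, centred at (origin_lon, origin_lat)."""
    x = (np.asarray(lon) - origin_lon) * KM_PER_DEG_LAT * np.cos(np.radians(origin_lat))
    y = (np.asarray(lat) - origin_lat) * KM_PER_DEG_LAT
    return x, y


def haversine_km_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances in km between points on the sphere."""
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * (
        np.sin(dlam / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
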