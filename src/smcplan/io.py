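"""Reading and writing household point tables, itineraries and cluster plans.

Two interchangeable plain-text point formats are supported:

* CSV with columns ``household_id, lon, lat, family_size, n_under5``;
* GeoJSON ``FeatureCollection`` of ``Point`` features carrying the same
  fields as properties.

Writing then reading either format is the identity on a village up to
floating-point coordinate representation.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .village import Household, Village, VillageValidationError

__all__ = [
    "read_households",
    "write_households",
    "village_to_frame",
    "write_itinerary_csv",
    "itinerary_to_geojson",
]

POINT_COLUMNS = ["household_id", "lon", "lat", "family_size", "n_under5"]


class PointFormatError(ValueError):
    """A household point file is malformed."""


def village_to_frame(village: Village) -> pd.DataFrame:
    """Household table as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [
            (h.household_id, h.lon, h.lat, h.family_size, h.n_under5)
            for h in village.households
        ],
        columns=POINT_COLUMNS,
    )


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".geojson", ".json"):
        return "geojson"
    raise PointFormatError(f"cannot infer point format from suffix {suffix!r}")


def _household_from_row(row: dict, index: int) -> Household:
    try:
        return Household(
            household_id=str(row["household_id"]),
            lon=float(row["lon"]),
            lat=float(row["lat"]),
            family_size=int(row["family_size"]),
            n_under5=int(row["n_under5"]),
        )
    except (KeyError, TypeError, ValueError, VillageValidationError) as exc:
        raise PointFormatError(f"row {index}: {exc}") from exc


def read_households(
    path: str | Path, format: str | None = None, name: str | None = None
) -> Village:
    """Read a village from a CSV or GeoJSON point file.

    Rows violating the household invariants (``family_size >= 1``,
    ``0 <= n_under5 <= family_size``) are rejected with a row-indexed
    :class:`PointFormatError`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    vname = name if name is not None else path.stem
    if fmt == "csv":
        frame = pd.read_csv(path)
        missing = [c for c in POINT_COLUMNS if c not in frame.columns]
        if missing:
            raise PointFormatError(f"missing columns: {missing}")
        households = [
            _household_from_row(row, i)
            for i, row in enumerate(frame[POINT_COLUMNS].to_dict("records"))
        ]
        return Village(vname, households)
    if fmt == "geojson":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("type") != "FeatureCollection":
            raise PointFormatError("expected a GeoJSON FeatureCollection")
        households = []
        for i, feat in enumerate(doc.get("features", [])):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise PointFormatError(f"row {i}: geometry is not a Point")
            lon, lat = geom["coordinates"][:2]
            props = dict(feat.get("properties") or {})
            props.update(lon=lon, lat=lat)
            households.append(_household_from_row(props, i))
        return Village(doc.get("name", vname), households)
    raise PointFormatError(f"unknown point format {fmt!r}")


def write_households(
    village: Village, path: str | Path, format: str | None = None
) -> Path:
    """Write a village as CSV or GeoJSON (format inferred from the suffix)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        village_to_frame(village).to_csv(path, index=False)
    elif fmt == "geojson":
        doc = {
            "type": "FeatureCollection",
            "name": village.name,
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [h.lon, h.lat]},
                    "properties": {
                        "household_id": h.household_id,
                        "family_size": h.family_size,
                        "n_under5": h.n_under5,
                    },
                }
                for h in village.households
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise PointFormatError(f"unknown point format {fmt!r}")
    return path


def write_itinerary_csv(itinerary, dm, path: str | Path) -> Path:
    """Visit schedule as CSV: rank, household_id, leg_km, cumulative_km."""
    index = {label: i for i, label in enumerate(dm.labels)}
    rows, cumulative = [], 0.0
    prev = None
    for rank, hid in enumerate(itinerary.order):
        leg = 0.0 if prev is None else float(dm.d[index[prev], index[hid]])
        cumulative += leg
        rows.append((rank, hid, leg, cumulative))
        prev = hid
    frame = pd.DataFrame(
        rows, columns=["rank", "household_id", "leg_km", "cumulative_km"]
    )
    frame.to_csv(Path(path), index=False)
    return Path(path)


def itinerary_to_geojson(itinerary, village: Village) -> dict:
    """Visit order as a GeoJSON LineString through the household locations."""
    by_id = {h.household_id: h for h in village.households}
    coords = [[by_id[hid].lon, by_id[hid].lat] for hid in itinerary.order]
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {
                    "total_km": itinerary.total_km,
                    "exact": itinerary.exact,
                    "n_households": len(itinerary.order),
                },
            }
        ],
    }
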