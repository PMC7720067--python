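"""Gridded population rasters and household extraction.

High-resolution settlement layers store estimated person counts per pixel.
For microplanning each populated pixel is treated as one household: the
pixel centre gives the dwelling's coordinates and the pixel value, rounded
to the nearest integer (minimum 1), gives the family size. Under-5 children
are then allocated across households with the same 18% largest-remainder
rule used by the synthetic generator.

Two raster encodings are read: single-band GeoTIFF (via ``tifffile``,
north-up rasters with ModelPixelScale/ModelTiepoint geo-tags) and the
plain-text ESRI ASCII grid (``.asc``), which is also the write format.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np

from .village import Household, Village, allocate_under5

__all__ = [
    "PopulationGrid",
    "RasterFormatError",
    "extract_households",
    "read_raster",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "rasterize_village",
]


class RasterFormatError(ValueError):
    """A raster file or grid description is malformed."""


@dataclasses.dataclass(frozen=True)
class PopulationGrid:
    """A single-band person-count grid with an affine georeferencing.

    ``transform`` is the 6-tuple ``(a, b, c, d, e, f)`` mapping fractional
    pixel indices (col, row; 0-based, top-left origin) to coordinates:
    ``x = a*col + b*row + c`` and ``y = d*col + e*row + f``. Pixel centres
    sit at ``(col + 0.5, row + 0.5)``.
    """

    values: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    crs: str = "EPSG:4326"
    nodata: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise RasterFormatError(f"grid must be 2-D, got shape {values.shape}")
        object.__setattr__(self, "values", values)
        if self.transform is None:
            raise RasterFormatError("grid has no affine transform")
        a, b, _, d, e, _ = self.transform
        if abs(a * e - b * d) < 1e-30:
            raise RasterFormatError("affine transform is not invertible")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        a, b, c, d, e, f = self.transform
        cc, rr = col + 0.5, row + 0.5
        return a * cc + b * rr + c, d * cc + e * rr + f

    def valid_mask(self) -> np.ndarray:
        mask = np.isfinite(self.values)
        if self.nodata is not None:
            mask &= self.values != self.nodata
        return mask


def extract_households(
    grid: PopulationGrid,
    min_persons: float = 1.0,
    under5_fraction: float = 0.18,
    name: str = "raster",
) -> Village:
    """Extract one household per populated pixel.

    Pixels with value >= ``min_persons`` (and not nodata) become households
    located at the pixel centre, with ``family_size = max(1, round(value))``.
    An empty result is a warning, not an error: settlement layers can
    legitimately contain no qualifying pixel in a window.
    """
    if min_persons <= 0:
        raise ValueError(f"min_persons must be > 0, got {min_persons}")
    mask = grid.valid_mask() & (grid.values >= min_persons)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        warnings.warn(f"no pixel with >= {min_persons} persons; empty village")
        return Village(name, [])
    sizes = np.maximum(1, np.rint(grid.values[rows, cols]).astype(int))
    under5 = allocate_under5(sizes, under5_fraction)
    width = max(4, len(str(rows.size)))
    households = []
    for i, (r, c) in enumerate(zip(rows.tolist(), cols.tolist())):
        lon, lat = grid.pixel_center(r, c)
        households.append(
            Household(
                household_id=f"px{i:0{width}d}",
                lon=lon,
                lat=lat,
                family_size=int(sizes[i]),
                n_under5=int(under5[i]),
            )
        )
    return Village(name, households)


def read_ascii_grid(path: str | Path) -> PopulationGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "xllcenter",
                "yllcenter",
                "cellsize",
                "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise RasterFormatError(f"ASCII grid missing header field {req!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.array([v for row in rows for v in row], dtype=float)
    if values.size != ncols * nrows:
        raise RasterFormatError(
            f"expected {ncols * nrows} values, found {values.size}"
        )
    values = values.reshape(nrows, ncols)
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0, y0 = header["xllcorner"], header["yllcorner"]
    else:  # cell-centre registration
        x0 = header["xllcenter"] - cell / 2.0
        y0 = header["yllcenter"] - cell / 2.0
    transform = (cell, 0.0, x0, 0.0, -cell, y0 + nrows * cell)
    return PopulationGrid(
        values=values,
        transform=transform,
        nodata=header.get("nodata_value"),
    )


def write_ascii_grid(grid: PopulationGrid, path: str | Path) -> Path:
    """Write a north-up square-pixel grid as an ESRI ASCII grid."""
    a, b, c, d, e, f = grid.transform
    if b or d or abs(a) != abs(e):
        raise RasterFormatError(
            "ASCII grids require square, axis-aligned pixels"
        )
    nrows, ncols = grid.shape
    nodata = grid.nodata if grid.nodata is not None else -9999.0
    values = np.where(np.isfinite(grid.values), grid.values, nodata)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(c)!r}\n")
        fh.write(f"yllcorner {float(f + e * nrows)!r}\n")
        fh.write(f"cellsize {float(a)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for row in values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    return path


def read_geotiff(path: str | Path) -> PopulationGrid:
    """Read a single-band north-up GeoTIFF using its geo-tags."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        if values.ndim == 3:
            values = values[..., 0]
        tags = {tag.name: tag.value for tag in page.tags.values()}
    scale = tags.get("ModelPixelScaleTag")
    tiepoint = tags.get("ModelTiepointTag")
    if scale is None or tiepoint is None:
        raise RasterFormatError(
            f"{path}: GeoTIFF lacks ModelPixelScale/ModelTiepoint geo-tags"
        )
    sx, sy = float(scale[0]), float(scale[1])
    i, j, _, x, y, _ = (float(v) for v in tiepoint[:6])
    transform = (sx, 0.0, x - i * sx, 0.0, -sy, y + j * sy)
    nodata = tags.get("GDAL_NODATA")
    return PopulationGrid(
        values=values,
        transform=transform,
        nodata=float(nodata) if nodata is not None else None,
    )


def read_raster(path: str | Path) -> PopulationGrid:
    """Dispatch on suffix: .asc -> ASCII grid, .tif/.tiff -> GeoTIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        return read_ascii_grid(path)
    if suffix in (".tif", ".tiff"):
        return read_geotiff(path)
    raise RasterFormatError(f"unknown raster format {suffix!r}")


def rasterize_village(
    village: Village, cellsize_deg: float = 1.0 / 3600.0, pad_cells: int = 1
) -> PopulationGrid:
    """Bin household family sizes onto a grid (sum of persons per pixel).

    The inverse of :func:`extract_households` up to pixel-centre snapping;
    useful for building known-truth rasters from synthetic villages.
    """
    if village.n_households == 0:
        raise ValueError("cannot rasterize an empty village")
    lonlat = village.lonlat
    west = lonlat[:, 0].min() - pad_cells * cellsize_deg
    north = lonlat[:, 1].max() + pad_cells * cellsize_deg
    ncols = int(np.ceil((lonlat[:, 0].max() - west) / cellsize_deg)) + pad_cells + 1
    nrows = int(np.ceil((north - lonlat[:, 1].min()) / cellsize_deg)) + pad_cells + 1
    values = np.zeros((nrows, ncols))
    for h in village.households:
        col = int((h.lon - west) / cellsize_deg)
        row = int((north - h.lat) / cellsize_deg)
        values[row, col] += h.family_size
    transform = (cellsize_deg, 0.0, west, 0.0, -cellsize_deg, north)
    return PopulationGrid(values=values, transform=transform)
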