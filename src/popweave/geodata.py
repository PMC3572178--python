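"""Grid and vector data model shared by every stage of the mapping pipeline.

The package works on a single axis-aligned grid: the origin is the outer
corner of cell (0, 0), cells are ``cell_size`` on a side, column index
increases with x and row index increases as y decreases (north-up raster
convention).  Cell (r, c) covers the half-open box
``[origin_x + c*s, origin_x + (c+1)*s) x (origin_y - (r+1)*s, origin_y - r*s]``
and its center sits at ``(origin_x + (c+0.5)*s, origin_y - (r+0.5)*s)``.

Rasters are stored as numpy arrays wrapped with a :class:`GridSpec`;
vector admin units are shapely geometries carried by :class:`AdminUnitSet`.
GeoTIFF round-trips go through :mod:`tifffile` with the standard
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags; vectors round-trip
through GeoJSON.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("popweave")

#: nodata sentinel for floating-point (population / error) rasters
NODATA_FLOAT = -9999.0
#: default nodata sentinel for categorical rasters
NODATA_INT = 255


class GridMismatchError(ValueError):
    """Raised when rasters that must share a grid do not."""


# ---------------------------------------------------------------------------
# grid + raster containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; both at least 1.
    origin_x, origin_y
        Coordinates of the outer (top-left) corner of cell (0, 0).
    cell_size
        Side length of a square cell in grid units.  The production value
        for ~100 m grids on a geographic CRS is 8.33e-4 degrees.
    crs_label
        Free-text CRS description; carried through I/O, never interpreted.
    nodata_code
        Integer sentinel for categorical rasters on this grid; never a
        valid class code.
    """

    n_rows: int
    n_cols: int
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    crs_label: str = ""
    nodata_code: int = NODATA_INT

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(xs, ys) arrays of shape (n_rows, n_cols) with cell-center coords."""
        s = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * s
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * s
        return np.broadcast_to(xs, self.shape).copy(), np.broadcast_to(ys[:, None], self.shape).copy()

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.origin_x, other.origin_x, rel_tol=0, abs_tol=1e-9 * self.cell_size)
            and math.isclose(self.origin_y, other.origin_y, rel_tol=0, abs_tol=1e-9 * self.cell_size)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
        )


def assert_same_grid(*rasters: "CategoricalRaster | ValueRaster") -> GridSpec:
    """Check that all rasters share one grid geometry; return it."""
    if not rasters:
        raise ValueError("no rasters given")
    base = rasters[0].grid
    for r in rasters[1:]:
        if not base.same_geometry(r.grid):
            raise GridMismatchError(f"grid mismatch: {base} vs {r.grid}")
    return base


@dataclass
class CategoricalRaster:
    """Integer-coded raster (land cover, climate zone, admin labels, masks)."""

    grid: GridSpec
    values: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("categorical raster values must be integers")

    @property
    def nodata(self) -> int:
        return self.grid.nodata_code

    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def codes_present(self) -> list[int]:
        vals = np.unique(self.values)
        return [int(v) for v in vals if v != self.nodata]

    def validate_legend(self) -> None:
        missing = [c for c in self.codes_present() if c not in self.legend]
        if missing:
            raise ValueError(f"codes without legend entry: {missing}")

    def copy(self) -> "CategoricalRaster":
        return CategoricalRaster(self.grid, self.values.copy(), dict(self.legend))


@dataclass
class ValueRaster:
    """Real-valued raster (persons per cell, or signed error per cell)."""

    grid: GridSpec
    values: np.ndarray
    nodata: float = NODATA_FLOAT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask()]

    def total(self) -> float:
        return float(self.valid_values().sum())


# ---------------------------------------------------------------------------
# admin units
# ---------------------------------------------------------------------------

@dataclass
class AdminUnit:
    """One census reporting polygon at some administrative level."""

    unit_id: str
    level: int
    geometry: BaseGeometry
    parent_id: str | None = None
    country: str = ""
    population: float | None = None

    @property
    def area(self) -> float:
        """Polygon area in squared grid units (planar)."""
        return float(self.geometry.area)


class AdminUnitSet:
    """Collection of admin units, possibly spanning several nested levels."""

    def __init__(self, units: Iterable[AdminUnit]):
        self.units: list[AdminUnit] = list(units)
        for level in self.levels():
            ids = [u.unit_id for u in self.at_level(level)]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate unit_ids at level {level}")
        by_level: dict[int, set[str]] = {
            lev: {u.unit_id for u in self.at_level(lev)} for lev in self.levels()
        }
        for u in self.units:
            if u.parent_id is not None:
                parents = by_level.get(u.level - 1, set())
                if parents and u.parent_id not in parents:
                    raise ValueError(
                        f"unit {u.unit_id} references missing parent {u.parent_id}"
                    )

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def levels(self) -> list[int]:
        return sorted({u.level for u in self.units})

    def at_level(self, level: int) -> list[AdminUnit]:
        return [u for u in self.units if u.level == level]

    def get(self, unit_id: str) -> AdminUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def aggregate_to_parents(self, fine_level: int) -> "AdminUnitSet":
        """Union fine-level geometries by parent, producing the coarse level."""
        fine = self.at_level(fine_level)
        if not fine:
            raise ValueError(f"no units at level {fine_level}")
        groups: dict[str, list[AdminUnit]] = {}
        for u in fine:
            if u.parent_id is None:
                raise ValueError(f"fine unit {u.unit_id} has no parent")
            groups.setdefault(u.parent_id, []).append(u)
        coarse = []
        for pid in sorted(groups):
            children = groups[pid]
            geom = shapely.unary_union([c.geometry for c in children])
            pops = [c.population for c in children]
            pop = sum(pops) if all(p is not None for p in pops) else None
            coarse.append(
                AdminUnit(
                    unit_id=pid,
                    level=fine_level - 1,
                    geometry=geom,
                    parent_id=None,
                    country=children[0].country,
                    population=pop,
                )
            )
        return AdminUnitSet(coarse)


# ---------------------------------------------------------------------------
# raster <-> vector operations
# ---------------------------------------------------------------------------

def rasterize_zones(units: AdminUnitSet | Sequence[AdminUnit], grid: GridSpec) -> CategoricalRaster:
    """Label each grid cell with the admin unit whose polygon contains its center.

    Cells outside every unit get the nodata code.  A cell center lying on a
    shared boundary is assigned to the unit with the lexicographically
    smallest ``unit_id`` (deterministic tie-break).  Units covering zero cell
    centers are logged — they cannot receive population.

    The returned legend maps label code -> unit_id; codes are assigned in
    lexicographic unit_id order starting at 1.
    """
    unit_list = list(units)
    if not unit_list:
        raise ValueError("empty unit set")
    levels = {u.level for u in unit_list}
    if len(levels) > 1:
        raise ValueError(f"units span multiple levels: {sorted(levels)}")

    out = np.full(grid.shape, grid.nodata_code, dtype=np.int32)
    xs, ys = grid.cell_centers()
    legend: dict[int, str] = {}
    empty: list[str] = []
    s = grid.cell_size
    ordered = sorted(unit_list, key=lambda u: u.unit_id)
    for code, unit in enumerate(ordered, start=1):
        legend[code] = unit.unit_id
        minx, miny, maxx, maxy = unit.geometry.bounds
        c0 = max(0, int(math.floor((minx - grid.origin_x) / s - 0.5)))
        c1 = min(grid.n_cols, int(math.ceil((maxx - grid.origin_x) / s + 0.5)))
        r0 = max(0, int(math.floor((grid.origin_y - maxy) / s - 0.5)))
        r1 = min(grid.n_rows, int(math.ceil((grid.origin_y - miny) / s + 0.5)))
        if c0 >= c1 or r0 >= r1:
            empty.append(unit.unit_id)
            continue
        sub_x = xs[r0:r1, c0:c1]
        sub_y = ys[r0:r1, c0:c1]
        # intersects (not contains) so boundary centers count; first-wins in
        # lexicographic order implements the tie-break
        hit = shapely.intersects_xy(unit.geometry, sub_x.ravel(), sub_y.ravel())
        hit = hit.reshape(sub_x.shape)
        target = out[r0:r1, c0:c1]
        assign = hit & (target == grid.nodata_code)
        if not assign.any():
            empty.append(unit.unit_id)
            continue
        target[assign] = code
    if empty:
        logger.warning(
            "rasterize_zones: %d unit(s) cover no cell centers and cannot "
            "receive population: %s", len(empty), empty
        )
    return CategoricalRaster(grid, out, legend)


@dataclass
class ZonalTable:
    """Cross-tabulation n_{j,c}: cells of class c inside admin unit j.

    ``table`` is indexed by unit_id with one column per class code; ``excluded``
    counts cells that were nodata in either input raster.
    """

    table: pd.DataFrame
    excluded: int = 0

    @property
    def unit_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def class_codes(self) -> list[int]:
        return [int(c) for c in self.table.columns]

    def unit_totals(self) -> pd.Series:
        """n_j: total tabulated cells per unit."""
        return self.table.sum(axis=1)

    def total_cells(self) -> int:
        return int(self.table.values.sum()) + self.excluded


def zonal_tabulate(zones: CategoricalRaster, classes: CategoricalRaster) -> ZonalTable:
    """Exact cell-count cross-tabulation of a zone raster against a class raster.

    Cells that are nodata in either raster are excluded and counted in
    ``ZonalTable.excluded``.
    """
    assert_same_grid(zones, classes)
    zv = zones.values.ravel()
    cv = classes.values.ravel()
    valid = (zv != zones.nodata) & (cv != classes.nodata)
    excluded = int((~valid).sum())
    zv, cv = zv[valid], cv[valid]
    if zv.size == 0:
        return ZonalTable(pd.DataFrame(dtype=np.int64), excluded)
    zc, zi = np.unique(zv, return_inverse=True)
    cc, ci = np.unique(cv, return_inverse=True)
    counts = np.zeros((zc.size, cc.size), dtype=np.int64)
    np.add.at(counts, (zi, ci), 1)
    idx = [zones.legend.get(int(z), str(int(z))) for z in zc]
    table = pd.DataFrame(counts, index=idx, columns=[int(c) for c in cc])
    return ZonalTable(table, excluded)


def mean_spatial_resolution(areas: Sequence[float]) -> float:
    """Average spatial resolution of a set of admin units, in the unit of
    sqrt(area): the square root of the mean unit area."""
    areas = list(areas)
    if not areas:
        raise ValueError("empty area list")
    if any(a <= 0 for a in areas):
        raise ValueError("all areas must be positive")
    return float(math.sqrt(sum(areas) / len(areas)))


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile with standard georeferencing tags)
# ---------------------------------------------------------------------------

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def write_geotiff(path, raster: CategoricalRaster | ValueRaster) -> None:
    """Write a single-band GeoTIFF; int32 for categorical, float32 for values.

    The class legend of a categorical raster travels in a JSON sidecar tag so
    round trips are lossless.
    """
    if isinstance(raster, CategoricalRaster):
        data = raster.values.astype(np.int32)
        nodata = raster.grid.nodata_code
        meta = {"crs_label": raster.grid.crs_label, "legend": {str(k): v for k, v in raster.legend.items()}}
    else:
        data = raster.values.astype(np.float32)
        nodata = raster.nodata
        meta = {"crs_label": raster.grid.crs_label}
    grid = raster.grid
    tags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(str(path), data, extratags=tags,
                     description=json.dumps(meta), metadata=None)


def read_geotiff(path) -> CategoricalRaster | ValueRaster:
    """Read a single-band GeoTIFF written by :func:`write_geotiff` (or any
    GeoTIFF carrying pixel-scale/tiepoint tags).  Integer data comes back as a
    CategoricalRaster, floating point as a ValueRaster."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = tags[_TAG_MODEL_TIEPOINT].value if _TAG_MODEL_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0.0)
        nodata_s = tags[_TAG_GDAL_NODATA].value if _TAG_GDAL_NODATA in tags else None
        meta = {}
        desc = page.description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    n_rows, n_cols = data.shape
    if np.issubdtype(data.dtype, np.integer):
        nodata = int(float(nodata_s)) if nodata_s is not None else NODATA_INT
        grid = GridSpec(n_rows, n_cols, float(tie[3]), float(tie[4]), float(scale[0]),
                        crs_label=meta.get("crs_label", ""), nodata_code=nodata)
        legend = {int(k): v for k, v in meta.get("legend", {}).items()}
        return CategoricalRaster(grid, data.astype(np.int32), legend)
    nodata = float(nodata_s) if nodata_s is not None else NODATA_FLOAT
    grid = GridSpec(n_rows, n_cols, float(tie[3]), float(tie[4]), float(scale[0]),
                    crs_label=meta.get("crs_label", ""))
    return ValueRaster(grid, data.astype(np.float64), nodata=nodata)


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def write_admin_geojson(path, units: AdminUnitSet) -> None:
    features = []
    for u in units:
        props = {
            "unit_id": u.unit_id,
            "level": u.level,
            "parent_id": u.parent_id,
            "country": u.country,
        }
        if u.population is not None:
            props["population"] = u.population
        features.append(
            {"type": "Feature", "geometry": geom_mapping(u.geometry), "properties": props}
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_admin_geojson(path) -> AdminUnitSet:
    with open(path, encoding="utf-8") as fh:
        fc = json.load(fh)
    units = []
    for feat in fc["features"]:
        p = feat["properties"]
        units.append(
            AdminUnit(
                unit_id=str(p["unit_id"]),
                level=int(p["level"]),
                geometry=geom_shape(feat["geometry"]),
                parent_id=(None if p.get("parent_id") in (None, "") else str(p["parent_id"])),
                country=str(p.get("country", "")),
                population=(float(p["population"]) if p.get("population") is not None else None),
            )
        )
    return AdminUnitSet(units)
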