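"""Seeded synthetic landscapes, admin hierarchies and census counts.

Everything the mapping pipeline consumes — a patchy multi-class land-cover
raster with cloud/no-data voids, blocky climate-zone bands, nested
rectangular admin units, urban-extent blobs, and census counts generated
from *known* per-zone per-class density weights — can be generated from a
single seeded :class:`SyntheticScenario`.  Because the true weights are
known, weight estimation and the whole accuracy protocol can be validated
end to end without any external data.

The generators are fixtures, not landscape models: patches come from seeded
random region growing (Eden growth with a fixed queue discipline so results
are platform-independent), climate zones are horizontal bands, urban extents
are disks.  Same scenario (seed included) always produces byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geodata import (
    AdminUnit,
    AdminUnitSet,
    CategoricalRaster,
    GridSpec,
    rasterize_zones,
)
from .gridding import CensusTable
from .landcover import DEFAULT_LEGEND, RURAL_SETTLEMENT, URBAN, fill_voids, refine_settlements
from .weights import WeightTable

#: default per-class density weights, persons per cell.  Settlement classes
#: dominate (urban ~ 40 persons/cell ~ 4000/km^2 at 100 m cells); water and
#: bare land are nearly empty.  The >= 10x spread between the settlement and
#: open-land classes is what gives dasymetric weighting its advantage.
_BASE_CLASS_WEIGHTS: dict[int, float] = {
    1: 0.2,    # water
    2: 0.6,    # forest
    3: 1.0,    # shrubland
    4: 1.5,    # grassland
    5: 4.0,    # cropland
    6: 0.4,    # wetland
    7: 0.3,    # bare
    URBAN: 40.0,
    RURAL_SETTLEMENT: 8.0,
}

#: multiplicative zone effect, cycled over climate zones: densities differ
#: across climate strata but class ordering is preserved.
_ZONE_MULTIPLIERS = (0.8, 1.0, 1.25, 0.9, 1.1)


def default_true_weights(n_classes: int = 9, n_zones: int = 3, scale: float = 1.0) -> WeightTable:
    """Complete ground-truth weight table over all (zone, class) pairs."""
    w = {}
    for z in range(1, n_zones + 1):
        mult = _ZONE_MULTIPLIERS[(z - 1) % len(_ZONE_MULTIPLIERS)]
        for c in range(1, n_classes + 1):
            w[(z, c)] = _BASE_CLASS_WEIGHTS.get(c, 1.0) * mult * scale
    return WeightTable.from_dict(w, provenance=["synthland"])


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study region.

    Defaults emulate the production setting at desk scale: a 128x128 grid of
    8.33e-4-degree cells (~100 m), the nine-class land-cover legend, three
    climate bands, and a two-level admin hierarchy of 30 coarse units each
    split into 4 fine units.  All draws are pure functions of ``seed``.
    """

    seed: int = 0
    n_rows: int = 128
    n_cols: int = 128
    cell_size: float = 8.33e-4
    n_classes: int = 9
    n_zones: int = 3
    n_coarse: int = 36
    n_fine_per_coarse: int = 4
    urban_blob_count: int = 5
    urban_blob_radius: int = 8
    void_fraction: float = 0.02
    noise_model: Literal["none", "poisson"] = "none"
    true_weights: WeightTable | None = None
    country: str = "synthland"

    def __post_init__(self) -> None:
        if not 0.0 <= self.void_fraction < 1.0:
            raise ValueError("void_fraction must be in [0, 1)")
        if self.noise_model not in ("none", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            self.n_rows,
            self.n_cols,
            origin_x=0.0,
            origin_y=self.n_rows * self.cell_size,
            cell_size=self.cell_size,
            crs_label="synthetic planar (degree-sized units)",
        )

    def weights(self) -> WeightTable:
        if self.true_weights is not None:
            if (self.true_weights.frame["weight"] < 0).any():
                raise ValueError("true weights must be nonnegative")
            return self.true_weights
        return default_true_weights(self.n_classes, self.n_zones)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

def _grow_patches(rng: np.random.Generator, shape: tuple[int, int],
                  patch_classes: list[int], n_patches: int) -> np.ndarray:
    """Eden-style region growing from random seed cells.

    Seed cells are drawn without replacement; the first len(patch_classes)
    patches cover every class at least once, the rest draw classes at random.
    Growth repeatedly picks a random frontier cell (swap-with-last pop, O(1))
    and colonizes its unlabelled 4-neighbours — deterministic for a given rng.
    """
    n_rows, n_cols = shape
    n_cells = n_rows * n_cols
    n_patches = min(n_patches, n_cells)
    labels = np.full(shape, -1, dtype=np.int32)
    flat_seeds = rng.choice(n_cells, size=n_patches, replace=False)
    order = rng.permutation(len(patch_classes))
    classes = [patch_classes[i] for i in order]
    while len(classes) < n_patches:
        classes.append(patch_classes[int(rng.integers(len(patch_classes)))])
    frontier: list[tuple[int, int]] = []
    for s_flat, cls in zip(flat_seeds, classes):
        r, c = divmod(int(s_flat), n_cols)
        labels[r, c] = cls
        frontier.append((r, c))
    while frontier:
        i = int(rng.integers(len(frontier)))
        frontier[i], frontier[-1] = frontier[-1], frontier[i]
        r, c = frontier.pop()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < n_rows and 0 <= cc < n_cols and labels[rr, cc] < 0:
                labels[rr, cc] = labels[r, c]
                frontier.append((rr, cc))
    return labels


def generate_landscape(
    s: SyntheticScenario,
) -> tuple[CategoricalRaster, CategoricalRaster, CategoricalRaster]:
    """(land cover, climate zones, urban extent) for a scenario.

    Land cover is grown as random patches over the non-urban classes (urban
    settlement only appears after :func:`popweave.landcover.refine_settlements`
    splits built cells with the urban extent); climate zones are contiguous
    horizontal bands; the urban extent is a union of disks.  A
    ``void_fraction`` share of land-cover cells is knocked out to nodata,
    emulating cloud/shadow voids.
    """
    grid = s.grid
    n_cells = grid.n_cells
    n_blob_cells = s.urban_blob_count * max(1, s.urban_blob_radius) ** 2
    if s.urban_blob_count and n_blob_cells > 4 * n_cells:
        raise ValueError("grid too small for the requested urban blobs")
    rng = np.random.default_rng([s.seed, 0])

    patch_pool = [c for c in range(1, s.n_classes + 1) if c != URBAN]
    n_patches = max(len(patch_pool), n_cells // 300)
    lc_vals = _grow_patches(rng, grid.shape, patch_pool, n_patches)

    # climate bands follow the coarse-unit row strips: climate varies at a far
    # coarser scale than census units, so no admin unit straddles a zone and
    # the unit-majority zone assignment used downstream is exact
    cr, _ = _near_square_factors(s.n_coarse)
    row_edges = np.round(np.linspace(0, grid.n_rows, cr + 1)).astype(int)
    strip = np.searchsorted(row_edges, np.arange(grid.n_rows), side="right") - 1
    zone_rows = (strip * s.n_zones // cr + 1).astype(np.int32)
    zone_vals = np.broadcast_to(zone_rows[:, None], grid.shape).astype(np.int32).copy()

    urban_vals = np.zeros(grid.shape, dtype=np.int32)
    rr, cc = np.mgrid[0:grid.n_rows, 0:grid.n_cols]
    for _ in range(s.urban_blob_count):
        cr = int(rng.integers(grid.n_rows))
        ccol = int(rng.integers(grid.n_cols))
        urban_vals[(rr - cr) ** 2 + (cc - ccol) ** 2 <= s.urban_blob_radius ** 2] = 1

    if s.void_fraction > 0:
        n_void = int(round(s.void_fraction * n_cells))
        if n_void >= n_cells:
            raise ValueError("void_fraction leaves no donor cells")
        void_flat = rng.choice(n_cells, size=n_void, replace=False)
        lc_vals.ravel()[void_flat] = grid.nodata_code

    legend = {c: DEFAULT_LEGEND.get(c, f"class_{c}") for c in range(1, s.n_classes + 1)}
    lc = CategoricalRaster(grid, lc_vals, legend)
    climate = CategoricalRaster(grid, zone_vals, {z: f"zone_{z}" for z in range(1, s.n_zones + 1)})
    urban = CategoricalRaster(grid, urban_vals, {0: "non_urban", 1: "urban"})
    return lc, climate, urban


# ---------------------------------------------------------------------------
# admin hierarchy
# ---------------------------------------------------------------------------

def _near_square_factors(n: int) -> tuple[int, int]:
    a = int(np.floor(np.sqrt(n)))
    while n % a:
        a -= 1
    return a, n // a


def generate_admin_hierarchy(s: SyntheticScenario) -> AdminUnitSet:
    """Two nested levels of rectangular admin units tiling the grid.

    Coarse units (level 2) are a near-square tiling of the grid; each is
    split into ``n_fine_per_coarse`` fine rectangles (level 3) with parent
    links.  Every fine unit is guaranteed to cover at least one cell center.
    """
    grid = s.grid
    cr, cc = _near_square_factors(s.n_coarse)
    fr, fc = _near_square_factors(s.n_fine_per_coarse)
    if cr * fr > grid.n_rows or cc * fc > grid.n_cols:
        raise ValueError(
            f"infeasible tiling: {cr * fr}x{cc * fc} fine blocks on a "
            f"{grid.n_rows}x{grid.n_cols} grid"
        )
    row_edges = np.round(np.linspace(0, grid.n_rows, cr + 1)).astype(int)
    col_edges = np.round(np.linspace(0, grid.n_cols, cc + 1)).astype(int)
    sgn = grid.cell_size
    units: list[AdminUnit] = []

    def rect(r0, r1, c0, c1):
        x0 = grid.origin_x + c0 * sgn
        x1 = grid.origin_x + c1 * sgn
        y0 = grid.origin_y - r0 * sgn
        y1 = grid.origin_y - r1 * sgn
        return box(x0, y1, x1, y0)

    ci = 0
    for i in range(cr):
        for j in range(cc):
            cid = f"c{ci:03d}"
            r0, r1 = row_edges[i], row_edges[i + 1]
            c0, c1 = col_edges[j], col_edges[j + 1]
            units.append(AdminUnit(cid, level=2, geometry=rect(r0, r1, c0, c1),
                                   country=s.country))
            f_rows = np.round(np.linspace(r0, r1, fr + 1)).astype(int)
            f_cols = np.round(np.linspace(c0, c1, fc + 1)).astype(int)
            if np.any(np.diff(f_rows) < 1) or np.any(np.diff(f_cols) < 1):
                raise ValueError("infeasible tiling: empty fine rectangle")
            fi = 0
            for a in range(fr):
                for b in range(fc):
                    units.append(
                        AdminUnit(f"{cid}_f{fi:02d}", level=3,
                                  geometry=rect(f_rows[a], f_rows[a + 1],
                                                f_cols[b], f_cols[b + 1]),
                                  parent_id=cid, country=s.country)
                    )
                    fi += 1
            ci += 1
    return AdminUnitSet(units)


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def generate_census(
    s: SyntheticScenario,
    lc: CategoricalRaster,
    climate: CategoricalRaster,
    units: AdminUnitSet,
    reference_year: int = 2008,
) -> CensusTable:
    """Fine-level census counts from the scenario's ground-truth weights.

    The expected count of unit j is  sum_c w_{z,c} * n_{j,c}  computed on the
    land cover actually passed in (normally the void-filled, settlement-
    refined raster the model will see, so noiseless recovery is exact).
    ``noise_model="poisson"`` draws seeded Poisson counts with that mean.
    """
    weights = s.weights()
    fine_level = max(units.levels())
    zones = rasterize_zones(units.at_level(fine_level), lc.grid)
    w_cell = weights.lookup_raster(climate, lc)
    rows = []
    for code in sorted(zones.legend):
        cells = zones.values == code
        if not cells.any():
            continue
        expected = float(w_cell[cells].sum())
        rows.append({"unit_id": zones.legend[code], "population": expected,
                     "reference_year": reference_year, "country": s.country})
    df = pd.DataFrame(rows)
    if s.noise_model == "poisson":
        rng = np.random.default_rng([s.seed, 2])
        df["population"] = rng.poisson(df["population"].to_numpy()).astype(float)
    return CensusTable(df)


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """Everything the pipeline needs, generated and prepared in one call."""

    scenario: SyntheticScenario
    lc_raw: CategoricalRaster        # with voids, before preparation
    lc: CategoricalRaster            # void-filled + settlement-refined
    climate: CategoricalRaster
    urban_extent: CategoricalRaster
    units: AdminUnitSet
    fine_zones: CategoricalRaster
    coarse_zones: CategoricalRaster
    census: CensusTable              # fine level, from true weights
    true_weights: WeightTable


def build_bundle(s: SyntheticScenario, reference_year: int = 2008) -> ScenarioBundle:
    """Generate a scenario and run the land-cover preparation, rasterization
    and census generation steps, returning all intermediate products."""
    lc_raw, climate, urban = generate_landscape(s)
    lc = fill_voids(lc_raw) if s.void_fraction > 0 else lc_raw.copy()
    lc = refine_settlements(lc, None, urban)
    units = generate_admin_hierarchy(s)
    fine_zones = rasterize_zones(units.at_level(3), s.grid)
    coarse_zones = rasterize_zones(units.at_level(2), s.grid)
    census = generate_census(s, lc, climate, units, reference_year)
    return ScenarioBundle(
        scenario=s, lc_raw=lc_raw, lc=lc, climate=climate, urban_extent=urban,
        units=units, fine_zones=fine_zones, coarse_zones=coarse_zones,
        census=census, true_weights=s.weights(),
    )


def scaled_scenario(s: SyntheticScenario, scale: float) -> SyntheticScenario:
    """Scenario with all true weights multiplied by ``scale`` (used to reach a
    prescribed unit-total magnitude in noise studies)."""
    base = s.weights()
    scaled = WeightTable(
        base.frame.assign(weight=base.frame["weight"] * scale),
        provenance=list(base.provenance),
    )
    return replace(s, true_weights=scaled)
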