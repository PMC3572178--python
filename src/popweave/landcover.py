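"""Land-cover preparation: reclassification, void filling, settlement refinement.

Satellite-derived land-cover products arrive with provider-specific class
codes, cloud/shadow voids, and a single undifferentiated "built" class.
This module turns them into the model's fixed nine-class legend:

====  =====================
code  class
====  =====================
1     water
2     forest
3     shrubland
4     grassland
5     cropland
6     wetland
7     bare
8     urban settlement
9     rural settlement
====  =====================

Codes 1-7 are configurable labels; 8 (URBAN) and 9 (RURAL_SETTLEMENT) are the
two settlement classes the redistribution model treats specially.  Built
areas inside an urban-extent footprint become URBAN, all other built areas
become RURAL_SETTLEMENT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geodata import CategoricalRaster, assert_same_grid

logger = logging.getLogger("popweave")

URBAN = 8
RURAL_SETTLEMENT = 9
SETTLEMENT_CLASSES = (URBAN, RURAL_SETTLEMENT)

DEFAULT_LEGEND: dict[int, str] = {
    1: "water",
    2: "forest",
    3: "shrubland",
    4: "grassland",
    5: "cropland",
    6: "wetland",
    7: "bare",
    URBAN: "urban_settlement",
    RURAL_SETTLEMENT: "rural_settlement",
}


@dataclass
class ReclassTable:
    """Mapping from source land-cover codes to the model legend.

    ``void_codes`` (cloud, shadow, provider no-data) are mapped to the nodata
    sentinel so :func:`fill_voids` can repair them afterwards.
    """

    mapping: dict[int, int]
    void_codes: set[int] = field(default_factory=set)

    @classmethod
    def identity(cls, codes) -> "ReclassTable":
        return cls({int(c): int(c) for c in codes})

    @classmethod
    def from_csv(cls, path) -> "ReclassTable":
        """CSV with columns source_code,target_code; rows whose target is the
        literal word ``void`` declare void codes."""
        df = pd.read_csv(path, dtype=str)
        mapping: dict[int, int] = {}
        voids: set[int] = set()
        for _, row in df.iterrows():
            src = int(row["source_code"])
            tgt = str(row["target_code"]).strip().lower()
            if tgt == "void":
                voids.add(src)
            else:
                mapping[src] = int(row["target_code"])
        return cls(mapping, voids)

    def to_csv(self, path) -> None:
        rows = [{"source_code": s, "target_code": t} for s, t in sorted(self.mapping.items())]
        rows += [{"source_code": v, "target_code": "void"} for v in sorted(self.void_codes)]
        pd.DataFrame(rows).to_csv(path, index=False)


def reclassify(lc: CategoricalRaster, table: ReclassTable,
               legend: dict[int, str] | None = None) -> CategoricalRaster:
    """Map source codes to target codes; void codes become the nodata sentinel.

    Raises ``ValueError`` listing any source codes present in the raster that
    are neither mapped nor declared void.
    """
    present = set(lc.codes_present())
    unmapped = sorted(present - set(table.mapping) - table.void_codes)
    if unmapped:
        raise ValueError(f"unmapped land-cover codes encountered: {unmapped}")
    out = np.full(lc.values.shape, lc.nodata, dtype=np.int32)
    for src, tgt in table.mapping.items():
        out[lc.values == src] = tgt
    for v in table.void_codes:
        out[lc.values == v] = lc.nodata
    return CategoricalRaster(lc.grid, out, legend or dict(DEFAULT_LEGEND))


def fill_voids(lc: CategoricalRaster) -> CategoricalRaster:
    """Fill every nodata cell with the class of its nearest non-void cell.

    Distance is Euclidean between cell centers.  Among equidistant donors the
    one with the smallest row index, then smallest column index, wins — a
    fixed tie-break so the fill is reproducible across platforms.  Non-void
    cells are never altered; the operation is idempotent.
    """
    void = lc.nodata_mask()
    if not void.any():
        return lc.copy()
    if void.all():
        raise ValueError("all-void raster: no donor cells to fill from")
    donors = np.argwhere(~void)  # (row, col), already in lexicographic order
    tree = cKDTree(donors.astype(np.float64))
    voids = np.argwhere(void)
    dist, nearest = tree.query(voids.astype(np.float64), k=1)
    out = lc.values.copy()
    vals = lc.values
    for (vr, vc), d, j in zip(voids, dist, nearest):
        # resolve ties exactly with integer squared distances
        cand = tree.query_ball_point((float(vr), float(vc)), d * (1 + 1e-9) + 1e-9)
        d2 = (donors[cand, 0] - vr) ** 2 + (donors[cand, 1] - vc) ** 2
        d2min = d2.min()
        tied = [cand[i] for i in np.flatnonzero(d2 == d2min)]
        best = min(tied)  # donor rows sorted lexicographically by (row, col)
        out[vr, vc] = vals[donors[best, 0], donors[best, 1]]
    return CategoricalRaster(lc.grid, out, dict(lc.legend))


def refine_settlements(
    lc: CategoricalRaster,
    built_masks: list[CategoricalRaster] | None,
    urban_extent: CategoricalRaster,
    settlement_classes: tuple[int, ...] = SETTLEMENT_CLASSES,
) -> CategoricalRaster:
    """Split built areas into urban vs rural settlement using an urban extent.

    A cell is *built* if its land-cover class is a settlement class or any of
    the supplied binary built/residential masks is 1 there (masks are fused
    with logical OR).  Built cells inside the urban extent become URBAN; built
    cells outside it become RURAL_SETTLEMENT.  Non-built cells pass through
    unchanged.
    """
    rasters = [lc, urban_extent] + list(built_masks or [])
    assert_same_grid(*rasters)
    built = np.isin(lc.values, settlement_classes)
    for m in built_masks or []:
        built |= m.values == 1
    urban = urban_extent.values == 1
    out = lc.values.copy()
    out[built & urban] = URBAN
    out[built & ~urban] = RURAL_SETTLEMENT
    legend = dict(lc.legend)
    legend.setdefault(URBAN, DEFAULT_LEGEND[URBAN])
    legend.setdefault(RURAL_SETTLEMENT, DEFAULT_LEGEND[RURAL_SETTLEMENT])
    return CategoricalRaster(lc.grid, out, legend)
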