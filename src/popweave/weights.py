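"""Per-climate-zone land-cover population density weights.

The dasymetric model assumes that within a climate zone z, every cell of
land-cover class c houses on average w_{z,c} persons.  A unit j with census
count T_j and per-class cell counts n_{j,c} then satisfies, approximately,

    T_j  ~=  sum_c  w_{z,c} * n_{j,c}

This module estimates w by nonnegative least squares per climate zone from
countries with fine-resolution census data, and averages weight tables
across countries.  Admin units train the zone that contains the majority of
their cells (ties go to the smaller zone code); their design-matrix counts
are restricted to cells inside that zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.linalg import matrix_rank
from scipy.optimize import nnls

from .geodata import CategoricalRaster, assert_same_grid

logger = logging.getLogger("popweave")


@dataclass
class WeightTable:
    """Density weights w_{z,c} (persons per cell) keyed by (climate zone,
    land-cover class), with per-zone estimation diagnostics and provenance."""

    frame: pd.DataFrame  # columns: climate_zone, land_cover, weight
    diagnostics: dict[int, dict] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"climate_zone", "land_cover", "weight"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"weight frame needs columns {sorted(required)}")
        if (self.frame["weight"] < 0).any():
            raise ValueError("weights must be nonnegative")

    @classmethod
    def from_dict(cls, w: dict[tuple[int, int], float], **kw) -> "WeightTable":
        rows = [
            {"climate_zone": z, "land_cover": c, "weight": float(v)}
            for (z, c), v in sorted(w.items())
        ]
        return cls(pd.DataFrame(rows), **kw)

    def as_dict(self) -> dict[tuple[int, int], float]:
        return {
            (int(r.climate_zone), int(r.land_cover)): float(r.weight)
            for r in self.frame.itertuples()
        }

    def zones(self) -> list[int]:
        return sorted(self.frame["climate_zone"].unique())

    def classes(self) -> list[int]:
        return sorted(self.frame["land_cover"].unique())

    def lookup(self, zone: int, lc_class: int) -> float:
        """w_{z,c} with fallback: exact pair, else the across-zone mean for
        the class, else 0 (unseen class houses nobody)."""
        d = self.as_dict()
        if (zone, lc_class) in d:
            return d[(zone, lc_class)]
        per_class = self.frame[self.frame["land_cover"] == lc_class]
        if len(per_class):
            return float(per_class["weight"].mean())
        return 0.0

    def lookup_raster(self, climate: CategoricalRaster, lc: CategoricalRaster) -> np.ndarray:
        """Vectorized per-cell weight array for a climate + land-cover pair of
        rasters; cells where either input is nodata get weight 0."""
        assert_same_grid(climate, lc)
        out = np.zeros(climate.grid.shape, dtype=np.float64)
        valid = ~(climate.nodata_mask() | lc.nodata_mask())
        pairs = np.unique(
            np.stack([climate.values[valid], lc.values[valid]], axis=1), axis=0
        )
        for z, c in pairs:
            w = self.lookup(int(z), int(c))
            if w:
                out[(climate.values == z) & (lc.values == c)] = w
        return out

    def to_csv(self, path) -> None:
        df = self.frame.copy()
        df["n_units"] = df["climate_zone"].map(
            lambda z: self.diagnostics.get(int(z), {}).get("n_units", "")
        )
        df["residual"] = df["climate_zone"].map(
            lambda z: self.diagnostics.get(int(z), {}).get("residual", "")
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeightTable":
        df = pd.read_csv(path)
        diag: dict[int, dict] = {}
        if "n_units" in df.columns:
            for z, sub in df.groupby("climate_zone"):
                row = sub.iloc[0]
                d = {}
                if pd.notna(row.get("n_units")) and str(row.get("n_units")) != "":
                    d["n_units"] = int(row["n_units"])
                if pd.notna(row.get("residual")) and str(row.get("residual")) != "":
                    d["residual"] = float(row["residual"])
                if d:
                    diag[int(z)] = d
        return cls(df[["climate_zone", "land_cover", "weight"]].copy(), diagnostics=diag)


def _majority_zone(zones: CategoricalRaster, climate: CategoricalRaster) -> dict[str, int]:
    """Assign each admin unit to the climate zone holding the majority of its
    cells; ties broken toward the smaller zone code."""
    zv, cv = zones.values.ravel(), climate.values.ravel()
    valid = (zv != zones.nodata) & (cv != climate.nodata)
    out: dict[str, int] = {}
    df = pd.DataFrame({"unit": zv[valid], "zone": cv[valid]})
    counts = df.groupby(["unit", "zone"]).size()
    for unit_code, sub in counts.groupby(level=0):
        sub = sub.droplevel(0)
        best = sub[sub == sub.max()].index.min()  # tie -> smaller zone code
        out[zones.legend.get(int(unit_code), str(int(unit_code)))] = int(best)
    return out


def estimate_weights(
    census,
    zones: CategoricalRaster,
    lc: CategoricalRaster,
    climate: CategoricalRaster,
    country: str | None = None,
) -> WeightTable:
    """Estimate w_{z,c} by per-zone nonnegative least squares.

    For each climate zone z the system  T_j = sum_c w_{z,c} n_{j,c}  is solved
    over the admin units assigned to z, with n_{j,c} counting only cells of
    unit j inside zone z.  Underdetermined systems are solved with the
    NNLS minimum-residual convention and flagged in the diagnostics; zones
    containing no units are omitted with a warning.

    ``census`` is a :class:`popweave.gridding.CensusTable` (or any object with
    a ``frame`` DataFrame carrying unit_id and population columns).
    """
    assert_same_grid(zones, lc, climate)
    frame = census.frame if hasattr(census, "frame") else census
    pop = dict(zip(frame["unit_id"].astype(str), frame["population"].astype(float)))
    if any(v < 0 for v in pop.values()):
        raise ValueError("census counts must be nonnegative")
    rasterized_units = set(zones.legend.get(c, str(c)) for c in zones.codes_present())
    missing = sorted(set(pop) - rasterized_units)
    if missing:
        raise ValueError(f"census units absent from the zones raster: {missing}")

    unit_zone = _majority_zone(zones, climate)

    zv, cv, lv = zones.values.ravel(), climate.values.ravel(), lc.values.ravel()
    valid = (zv != zones.nodata) & (cv != climate.nodata) & (lv != lc.nodata)
    df = pd.DataFrame({"unit": zv[valid], "zone": cv[valid], "lc": lv[valid]})
    counts = df.groupby(["unit", "zone", "lc"]).size()

    code_to_id = {c: zones.legend.get(c, str(c)) for c in zones.codes_present()}
    all_zones = sorted(set(int(z) for z in climate.codes_present()))

    rows = []
    diagnostics: dict[int, dict] = {}
    for z in all_zones:
        unit_codes = [
            c for c, uid in code_to_id.items()
            if uid in pop and unit_zone.get(uid) == z
        ]
        if not unit_codes:
            logger.warning("climate zone %d has no training units; omitted", z)
            continue
        unit_set = set(unit_codes)
        classes = sorted({
            int(lc_code)
            for (uc, zz, lc_code) in counts.index
            if uc in unit_set and zz == z
        })
        if not classes:
            logger.warning("climate zone %d has no tabulated cells; omitted", z)
            continue
        design = np.zeros((len(unit_codes), len(classes)), dtype=np.float64)
        target = np.zeros(len(unit_codes), dtype=np.float64)
        cls_idx = {c: i for i, c in enumerate(classes)}
        for i, uc in enumerate(unit_codes):
            target[i] = pop[code_to_id[uc]]
            sub = counts.loc[uc]
            if z in sub.index.get_level_values(0):
                for lc_code, n in sub.xs(z, level="zone").items():
                    design[i, cls_idx[int(lc_code)]] = n
        w, rnorm = nnls(design, target)
        underdetermined = matrix_rank(design) < len(classes)
        diagnostics[z] = {
            "n_units": len(unit_codes),
            "residual": float(rnorm),
            "underdetermined": bool(underdetermined),
        }
        if underdetermined:
            logger.warning(
                "climate zone %d: design rank %d < %d classes; NNLS solution "
                "is one of many", z, matrix_rank(design), len(classes)
            )
        for c in classes:
            rows.append({"climate_zone": z, "land_cover": c, "weight": float(w[cls_idx[c]])})
    if not rows:
        raise ValueError("no climate zone had any training units")
    return WeightTable(
        pd.DataFrame(rows),
        diagnostics=diagnostics,
        provenance=[country] if country else [],
    )


def combine_weights(tables: list[WeightTable]) -> WeightTable:
    """Average weight tables across countries: for each (zone, class) pair the
    unweighted arithmetic mean of the weights present; pairs present in a
    single table pass through unchanged."""
    if not tables:
        raise ValueError("no weight tables to combine")
    if len(tables) == 1:
        t = tables[0]
        return WeightTable(t.frame.copy(), diagnostics=dict(t.diagnostics),
                           provenance=list(t.provenance))
    stacked = pd.concat([t.frame for t in tables], ignore_index=True)
    mean = (
        stacked.groupby(["climate_zone", "land_cover"], as_index=False)["weight"].mean()
    )
    provenance = [p for t in tables for p in t.provenance]
    return WeightTable(mean, provenance=provenance)
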