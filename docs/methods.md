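# Methods

## Model and procedure

`popweave` implements dasymetric areal interpolation of census counts: the
population of an administrative unit is redistributed over the grid cells it
contains, in proportion to per-cell density weights derived from ancillary
land-cover and climate data. The pipeline has five stages, matching the
module layout:

1. **Land-cover preparation** (`landcover`). Source classes are reclassified
   into a fixed nine-class legend (codes 1–7 configurable open-land classes;
   8 = urban settlement, 9 = rural settlement). Cloud/shadow/no-data voids
   are filled by nearest-neighbour donor assignment, and built areas — the
   union of settlement-classed cells and any binary built/residential
   masks — are split into urban vs rural settlement by overlay with an
   urban-extent footprint.
2. **Weight estimation** (`weights`). For each climate zone *z* the system
   *T*<sub>j</sub> = Σ<sub>c</sub> *w*<sub>z,c</sub>·*n*<sub>j,c</sub> is
   solved by nonnegative least squares over the training units assigned to
   that zone. A unit trains the zone holding the majority of its cells
   (ties to the smaller zone code) and contributes only the cells inside
   that zone to its design row. Weight tables from several training
   countries are combined by unweighted arithmetic means per (z, c) pair.
3. **Projection** (`gridding`). Unit counts are carried to the target year
   with compound growth *P* = *P*<sub>d</sub>(1+*r*)<sup>t</sup>, the rate
   chosen per unit by whether the unit coincides with the urban extent
   (any overlapping cell ⇒ urban). Growth is applied at the unit level
   before redistribution; because redistribution is linear in the unit
   count, projecting first and scaling after gridding are identical, and
   the same holds for national-total adjustment, which is a uniform rescale
   of the finished raster.
4. **Redistribution** (`gridding`). Three methods share one contract —
   per-unit mass conservation and nonnegativity: the dasymetric model
   (weights as above), areal weighting (*T*<sub>j</sub>/*n*<sub>j</sub> per
   cell), and an urban-concentration baseline that places a fixed share of
   each unit's count uniformly on its urban-extent cells and the remainder
   uniformly elsewhere.
5. **Accuracy assessment** (`accuracy`). Fine-level counts are summed to
   their parent units; the map is rebuilt from the coarse counts alone; the
   modelled cells are summed back within each fine unit and compared with
   the held-back fine counts via RMSE, %RMSE (= 100·RMSE / mean observed),
   MAE, and Pearson's *r*. Absolute errors per method are compared with the
   Kruskal-Wallis test (tie-corrected, chi-square p on k−1 df) and the
   Siegel–Castellan multiple-comparison-of-mean-ranks post-hoc:
   methods a, b differ at level α when
   |R̄<sub>a</sub> − R̄<sub>b</sub>| ≥ z<sub>1−α/(k(k−1))</sub> ·
   √(N(N+1)/12 · (1/n<sub>a</sub> + 1/n<sub>b</sub>)). The critical
   difference uses the standard (uncorrected-for-ties) standard error, as
   in the common R implementations of this procedure.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `cell_size` | 8.33×10⁻⁴ grid units | cell side; the production value in degrees (~100 m at the equator) |
| `urban_share` | 0.5 | fraction of a unit's count concentrated on urban cells in the GRUMP-style baseline; configurable per run |
| `alpha` | 0.05 | significance level of the post-hoc pairwise comparisons |
| `nodata` | 255 (int), −9999.0 (float) | reserved sentinels, never valid codes |

The urban-concentration baseline is deliberately simplified: true
settlement-based products allocate per-settlement population estimates,
which require data this package does not model. The single `urban_share`
parameter is this package's stand-in and is not a claim about any published
product's algorithm.

## Weight estimation: design choices

The estimator is per-zone NNLS of unit totals on per-class cell counts —
the simplest formulation that yields persons-per-cell weights directly
usable by redistribution, keeps every weight nonnegative, and makes
noiseless recovery exact when the per-zone design has full column rank.
Underdetermined zones (fewer independent unit compositions than classes)
are solved with the NNLS convention and flagged in the diagnostics rather
than refused, since redistribution only needs *a* consistent weight set.
At prediction time a (z, c) pair absent from the table falls back to the
across-zone mean for class c, then to zero. Cross-zone units are not split
between zones; with climate varying at a much coarser scale than census
units this assignment is exact, and the restriction of design counts to the
assigned zone bounds the damage when it is not.

## Rasterization and void-fill conventions

A cell belongs to the polygon containing its center; a center on a shared
boundary goes to the lexicographically smallest `unit_id`, making
rasterization deterministic byte-for-byte. The grid origin is the outer
corner of cell (0, 0), rows increase away from `origin_y` (north-up), and
cell area is treated as constant (planar approximation) — on geographic
grids spanning wide latitude ranges users should supply equal-area inputs
or accept the approximation, which is documented rather than corrected.

Void filling assigns each nodata cell the class of its nearest donor by
Euclidean distance between cell centers; among exactly equidistant donors
(squared distances are compared in integer arithmetic, so ties are exact)
the smallest row index then column index wins. The operation is idempotent
and never touches non-void cells. The implementation resolves each void
against a KD-tree of donors plus an exact tie scan; it is O(V·log D) in
typical rasters and was verified against an exhaustive donor scan on all
4×4 rasters with up to three voids.

## The synthetic generator

The generator emulates the *structure* of the production inputs, not their
geography: land cover is grown as seeded random patches (Eden growth with a
fixed queue discipline, hence platform-independent), climate zones are
contiguous horizontal bands aligned with the coarse-unit row strips —
climate varies at a far coarser scale than census units, so no unit
straddles a zone — urban extents are disks, admin units are two levels of
nested rectangles (36 coarse × 4 fine by default, giving every zone 12
coarse units ≥ the 9 land-cover classes so the coarse-level fit is
determined), and census counts are the exact linear form
Σ *w*<sub>z,c</sub>·*n*<sub>j,c</sub> of known ground-truth weights,
optionally with Poisson noise. Default true weights span water (0.2
persons/cell) to urban settlement (40 persons/cell), a 200-fold spread with
zone multipliers 0.8/1.0/1.25 — strongly class-dependent density is the
regime in which dasymetric weighting is expected to beat uniform spreading.

What passing tests on these fixtures demonstrates: correctness of the
estimators and redistribution arithmetic, conservation, determinism, and
the qualitative method ordering under class-dependent density. What they do
not demonstrate: performance on real landscapes, where land-cover classes
are misclassified, census geographies are inaccurate or misaligned,
density varies within classes, and growth rates vary sub-nationally.

## Problem sizes

The default scenario is a 128×128 grid (16 384 cells, 144 fine units); the
end-to-end checks and the acceptance script use 256×256 (65 536 cells).
Replicate studies (weight recovery under Poisson noise, method ordering)
use 20 seeded replicates at the default size. These sizes make every
experiment reproducible on a laptop in seconds while keeping each zone's
design matrix comfortably overdetermined.

## Numerical notes and degenerate inputs

- Per-unit conservation holds to ~10⁻¹⁵ relative (float64 summation); the
  contract asserts ≤10⁻⁹.
- A unit whose cells all carry zero weight falls back to uniform spread —
  conservation is prioritized over strict weight adherence — and is logged.
- Pearson's *r* is reported as undefined (None), not 0, when either series
  is constant; %RMSE is undefined when mean observed is 0. Both *r* and
  *r*² are reported, since published accuracy tables are not always
  explicit about which they print.
- With every value identical across all groups, the rank comparison
  reports H = 0, p = 1, no significant pairs.
- An optional largest-remainder integerization is provided for users who
  need integer persons; it is off by default — the products are
  real-valued densities.

## Known limitations

- No reprojection or resampling: all rasters entering one model run must
  already share a grid (asserted). Users preparing real 30 m land cover
  must resample upstream; the resampling rule (majority vs nearest) is
  their choice and affects class proportions.
- Shapefile input is not supported; vectors are GeoJSON.
- The GRUMP-style baseline's `urban_share` is a scalar simplification (see
  above).
- Growth rates are national urban/rural only; sub-national variation is
  out of scope.
- Aggregation-based validation inherits the modifiable areal unit problem:
  scores depend on the size and shape of the units used.
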