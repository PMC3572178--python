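# popweave

Dasymetric population mapping for fine-resolution gridded population
datasets. `popweave` redistributes administrative-unit census counts onto a
regular grid (~100 m cells in production use) using climate-zone-stratified
land-cover density weights, alongside two widely used baselines — areal
weighting (the GPW approach) and urban-concentration redistribution (a
GRUMP-style scheme) — and ships the aggregation-based cross-validation
framework used to compare them. A seeded synthetic-data generator provides
landscapes, nested admin hierarchies and census counts with *known* density
weights, so the entire pipeline is testable end to end without any external
downloads.

It is aimed at researchers in spatial demography, epidemiology and
development planning who need people-per-cell rasters from census polygons,
and at anyone evaluating redistribution methods.

## The model

Within climate zone *z*, each cell of land-cover class *c* is assumed to
house on average *w*<sub>z,c</sub> persons. A unit *j* with census count
*T*<sub>j</sub> and per-class cell counts *n*<sub>j,c</sub> then satisfies

&nbsp;&nbsp;&nbsp;&nbsp;*T*<sub>j</sub> ≈ Σ<sub>c</sub> *w*<sub>z,c</sub> · *n*<sub>j,c</sub>

The weights are estimated per climate zone by nonnegative least squares from
countries with fine-resolution census data and averaged across countries.
Redistribution then assigns cell *i* of unit *j*

&nbsp;&nbsp;&nbsp;&nbsp;pop<sub>i</sub> = *T*<sub>j</sub> · *w*<sub>z(i),c(i)</sub> / Σ<sub>k∈j</sub> *w*<sub>z(k),c(k)</sub>

which conserves each unit's count exactly (the pycnophylactic property).
Counts can first be projected through time with compound urban/rural growth,
*P* = *P*<sub>d</sub>(1+*r*)<sup>t</sup>, where *r* is the urban or rural
national growth rate depending on whether the unit coincides with an
urban-extent footprint, and outputs can be rescaled to a national total.

Accuracy is assessed by aggregating fine census units to their parents,
re-modelling from the coarse counts alone, and scoring the summed cell
estimates within each fine unit against the held-back fine counts with
RMSE, %RMSE (RMSE as a percentage of the mean observed unit population),
MAE and Pearson's *r*; error distributions across methods are compared with
the Kruskal-Wallis rank test plus the Siegel–Castellan
critical-difference post-hoc on mean ranks.

## Worked example

```python
import popweave as pw

scenario = pw.SyntheticScenario(seed=1, noise_model="poisson")
bundle = pw.build_bundle(scenario)   # landscape, admin units, census, rasters

# hold back the fine level: model from the coarser level only
coarse_census, _ = pw.aggregate_units(bundle.census, bundle.units)
wt = pw.estimate_weights(coarse_census, bundle.coarse_zones, bundle.lc, bundle.climate)

pops = {
    "asiapop": pw.dasymetric_redistribute(coarse_census, bundle.coarse_zones,
                                          bundle.lc, bundle.climate, wt),
    "gpw": pw.areal_redistribute(coarse_census, bundle.coarse_zones),
    "grump": pw.grump_redistribute(coarse_census, bundle.coarse_zones,
                                   bundle.urban_extent, 0.5),
}
pairs = {m: pw.evaluate(p, bundle.fine_zones, bundle.census, m) for m, p in pops.items()}
print(pw.build_report(pairs).summary())
```

prints

```
method accuracy (fine-unit observed vs estimated totals)

     asiapop: RMSE=23.68  %RMSE=6.08%  MAE=15.52  r=0.999  (n=144)
         gpw: RMSE=352.65  %RMSE=90.54%  MAE=198.15  r=0.692  (n=144)
       grump: RMSE=234.46  %RMSE=60.20%  MAE=151.62  r=0.879  (n=144)

Kruskal-Wallis on absolute errors: H=147.4080, p=9.79e-33
  asiapop vs gpw: |mean-rank diff|=157.41 vs critical 35.22 -> differ (alpha=0.05)
  asiapop vs grump: |mean-rank diff|=151.86 vs critical 35.22 -> differ (alpha=0.05)
  gpw vs grump: |mean-rank diff|=5.55 vs critical 35.22 -> no significant difference (alpha=0.05)
```

The dasymetric model, told only the coarse counts, reconstructs the fine
counts almost exactly (its RMSE comes from the Poisson noise in the
held-back census); uniform spreading is an order of magnitude worse, urban
concentration sits in between, and the two baselines are statistically
indistinguishable from each other on mean ranks.

The same pipeline is available from the shell:

```bash
popweave synth --seed 1 --out data/
popweave prep-landcover --lc data/landcover_raw.tif \
    --urban-extent data/urban_extent.tif --out data/landcover.tif
popweave rasterize --units data/admin.geojson --level 3 \
    --like data/landcover.tif --out data/zones3.tif
popweave estimate-weights --census data/census_fine.csv --zones data/zones3.tif \
    --lc data/landcover.tif --climate data/climate.tif --out data/weights.csv
popweave grid --method asiapop --census data/census_fine.csv --zones data/zones3.tif \
    --lc data/landcover.tif --climate data/climate.tif \
    --weights data/weights.csv --out data/pop.tif
popweave assess --units data/admin.geojson --census data/census_fine.csv \
    --lc data/landcover.tif --climate data/climate.tif \
    --urban-extent data/urban_extent.tif --out data/assessment/
```

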