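# isomove

Stable-hydrogen-isotope geographic assignment and seasonal range delineation
for migratory bats.

## The problem

Tree-roosting migratory bats are found as carcasses at wind-energy
facilities far outside their described ranges, and nothing about a carcass
says where the animal spent the summer.  Fur keratin does: it is grown
during a summer molt and records the stable-hydrogen-isotope composition
(δ²H, ‰ vs VSMOW-SLAP) of local precipitation, which varies strongly and
predictably across a continent.  This package implements the inference
chain from fur δ²H values to geographic origins, and from dated occurrence
records to seasonal range polygons, for researchers quantifying cryptic
migration from carcass and occurrence data.

## The model

**Origin assignment.**  A precipitation isoscape (gridded δ²H_precip) is
reprojected to an Albers equal-area grid and rescaled cellwise to an
expected-fur surface through a linear calibration fitted on known-origin
samples,

    δ²H_fur = β₀ + β₁ · δ²H_precip + ε,   ε ~ N(0, σ_res²),

with assignment error σ = √(σ_res² + σ_analytical²) (σ_analytical = 2.3‰
mass-spectrometry precision).  For a measured value *y* the probability of
origin in cell *c* is the normalized normal likelihood

    p_c ∝ exp(−(y − μ_c)² / 2σ²),

restricted to a 250-km buffer around the known range (a 100-km alpha hull
of occurrence-county centroids).  Each surface is transformed to its
within-surface empirical CDF, and a single quantile threshold is calibrated
on known-origin test samples so that thresholded "likely regions" contain
the true origin for ≥ 75% of the test set.

**Movement summaries.**  Direction of origin: 10,000 bootstrap draws of
origins weighted by p_c; a replication indicates a southerly origin when the
travel azimuth (ellipsoid shortest path from drawn origin to carcass site)
is within 90° of due north, and a sample is called south/north when > 75% of
replications agree.  Minimum travel: the shortest WGS84 geodesic from the
carcass site to any likely-region cell center — a deliberate lower bound.

**Seasonal ranges.**  Occurrences are binned into spring/summer
(Mar 16–Aug 5), autumn (Aug 6–Nov 15) and winter (Nov 16–Mar 15); each
season's extent of occurrence is a dynamic alpha hull (smallest alpha whose
shape is a single polygon holding ≥ 95% of points, 50-km point buffer,
clipped to land).  Year-round range = summer ∩ winter; season-only ranges
subtract the union of the other seasons; areas are planar km² in the
equal-area frame.

All inputs can be generated synthetically (`isomove.synthetic`), so the
whole chain runs without downloads.

## Worked example

The analysis drivers run the chain on a synthetic world (isoscape gradient
−1.5‰/°latitude, rescaling truth β₀ = −40, β₁ = 0.6, residual SD 10‰,
17 migrant carcasses displaced 500 km north of their origins):

```
$ python analysis/01_simulate.py --seed 1
$ python analysis/02_assign_origins.py
rescaling: intercept -32.95, slope 0.754, residual sd 11.57 permil (n=200)
assignment sigma: 11.80 permil; quantile threshold: 0.425
17 carcass samples: 14 classified south, 0 north, 3 unclassified
minimum travel distance: median 67 km, max 746 km; 7 of 17 samples > 100 km
$ python analysis/03_seasonal_ranges.py
...
year-round (summer ∩ winter): 1,328,890 km2
autumn-only: 1,759,095 km2
winter-only: 0 km2 (computed but reported separately; excluded from subsequent analyses)
$ python analysis/04_fatality_table.py
...
grand total: 49 carcasses
```

Reading the output: the rescaling estimates sit within sampling error of
the generating truth; the 0.425 quantile threshold is the largest value
keeping ≥ 75% of the known-origin test samples inside their likely regions;
14 of 17 migrants are confidently assigned southerly origins (the remainder
stay unclassified rather than being forced); and the seasonal overlay
reproduces the structure the truth polygons encode — a large autumn-only
extension, and a winter range nested inside summer so the winter-only
remainder is empty.  Outputs land in `results/` (summary CSVs, GeoJSON
polygons with `area_km2` properties, ASCII-grid rasters).

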