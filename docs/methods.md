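# Methods

This note documents the models, conventions and numerical choices behind
`rangestack`, in the spirit of a statistical package's methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

All layers share one raster data model: row-major grids with row 0
northernmost, square cells, and an explicit nodata sentinel.  Cell
`(r, c)` covers the half-open square
`[x0 + c·s, x0 + (c+1)·s) × (y0 − (r+1)·s, y0 − r·s]`; a point belongs to
the unique cell containing it, and points on the grid's eastern or
southern outer boundary are outside.  This single point→cell rule is used
by thinning, rasterization and raster sampling, so the three can never
disagree about which cell a site occupies.

Two CRS modes exist.  The synthetic system uses a flat `local-km` frame
(distances Euclidean, the grid centred on the origin so coordinates stay
within geographic bounds); real-data mode uses `wgs84`, where the only
metric operation — the degenerate-case buffer — goes through a spherical
azimuthal equidistant projection centred on the point set, written here
directly from the standard trigonometric forms.

Rasters are stored as ESRI ASCII grids: a plain-text format whose header
is exactly the georeferencing of the data model, readable by any GIS.
The CRS tag travels in a `.prj` sidecar.  Vector layers are GeoJSON;
geometry predicates and hulls come from shapely/GEOS.

## Cleaning and thinning

Cleaning removes rows with missing/unparseable or out-of-range
coordinates, unknown activity labels, and exact duplicates on
(species, lon, lat), each counted by reason so
accepted + rejected = input holds exactly.  Thinning keeps at most one
record per species per analysis cell.  It is cell-based, not
pairwise-distance based: the analysis grid defines the thinning distance,
the procedure is deterministic (first record in input order wins), and it
is idempotent.  A permutation of the input can change which record
represents a cell but never how many are retained.

## Range construction

Per biome with ≥1 record: the convex hull of the biome's records, or — 
when the hull has zero area (one or two distinct sites, or collinear
sites) — the union of 50-km disks around the degenerate hull geometry
(buffer_radius_km, default 50).  Hulls are clipped to their biome
polygon, so a range cannot leak into an unoccupied biome; a config flag
(`clip_to_biome`) disables this, since grouping-without-clipping is also
a defensible reading of the approach.  Buffers use 16 circle segments per
quadrant (area error of the polygonal disk < 0.2%).

The temperature envelope is computed once per species from all its
retained occurrences pooled across biomes, with linear-interpolation
quantiles (index h = (n−1)p + 1, the default of mainstream numerical
environments) at 2.5% and 97.5%.  Temperature at a site is the value of
the cell containing it; no interpolation.  Rasterization marks a cell
present iff its centre is covered by the polygon union; the envelope then
zeroes cells whose temperature is outside [t_low, t_high] or nodata.

Two small-sample consequences are worth knowing.  With a single
occurrence the envelope collapses to that site's temperature and the
buffered range keeps at least the occurrence cell.  With exactly two
occurrences at different temperatures, the interpolated quantiles lie
strictly *between* the two observed values, so both sites can be clipped
and the range can be empty — a faithful property of the quantile rule,
not a defect of the implementation.  Likewise the hull recovers a
species' true range only to the extent the range is sampled: ≥90%
cell recovery is reached when sampling is dense and spatially spread
relative to the range (the test suite demonstrates this at ~400 raw
records per species with wide sampling clusters), not at any fixed record
count.

## Richness

Richness rasters are integer sums of binary range rasters within the
study-area mask (nodata −1 outside), so conservation
(Σ_cells richness = Σ_species range cells) and group additivity
(all = diurnal + nocturnal per cell) are exact integer identities, and
the tests assert them exactly.  The mask defaults to the union of biome
polygons when no separate mask is supplied.

## Predictor layers

*Climate-change velocity.*  With only two climate states (present, LGM =
21 000 yr BP) the temporal rate is |current − past| / years.  The spatial
gradient is computed on the **current** surface (configurable:
current/past/mean) with the Horn 3×3 kernel in the interior — the
standard GIS slope operator — and one-sided/central differences on the
border ring; a central-difference kernel is available by config.  Cells
flatter than `gradient_floor` (default 1e−6 unit/km) use the floor, so
velocity stays finite over flat fields; the floor, not cell dropping, is
the chosen degenerate-case policy.  Velocity is emitted in km/yr.  Note
that velocity layers are intrinsically heavy-tailed: a handful of
near-flat cells sit hundreds of interquartile ranges above the median.
Multiple paleoclimate sources are combined by cell-wise arithmetic mean
before the velocity computation (nodata if any source is nodata).

*Topographic heterogeneity.*  Sample standard deviation (denominator
n−1) of the f² fine-DEM cells under each coarse cell; the fine cell size
must divide the coarse one exactly.  Blocks with fine nodata use the
remaining cells and become nodata below two valid cells.  The statistic
is invariant to elevation offsets and scales linearly with elevation
scaling.

*Uplift age.*  Cell value = age (Myr) of the mountain polygon covering
the cell centre; 0 where no polygon; the older age wins overlaps.

The seven layers (temperature, precipitation, topo_heterogeneity, ndvi,
temperature_velocity, precipitation_velocity, uplift_age) assemble into a
stack whose validity mask is the intersection of the per-layer masks.

## Driver models

Counts per valid cell are fitted by Poisson IRLS (statsmodels) with a log
link; quasi-Poisson enters through the Pearson dispersion
φ̂ = X²/(n−p), which multiplies the standard errors by √φ̂ — the point
estimates are exactly the Poisson MLEs.  Convergence is judged on
parameter stability (max |Δβ| < 1e−8 within 100 iterations; if the
deviance-based stop has not triggered, one extra IRLS step measures Δβ
directly), and non-convergence is an error carrying the deviance trace.
AIC under quasi-likelihood is formally undefined; the tabulated AIC is
that of the Poisson likelihood at the (identical) estimates, which is the
convention of applied tables that show AIC alongside quasi-Poisson fits,
and the output metadata says so.

Predictors are z-scored before fitting by default (config `standardize`);
the quadratic form is intercept + x + x² of the standardized predictor,
and the quadratic row reports the x² coefficient as its slope with the
linear term emitted alongside.  Raw and adjusted explained deviance are
both reported (D² = 1 − D_res/D_null;
D²_adj = 1 − ((n−1)/(n−p))(1−D²)) rather than guessing which one a
given published table shows.  Significance stars use two-sided normal
tails at 0.05/0.01/0.001.  The sampling unit is the raster cell, with no
spatial-autocorrelation correction — matching the method being
re-implemented; a `subsample_fraction` exists for speed, not inference.

VIF_j = 1/(1−R²_j) from the OLS regression of predictor j on the others
plus intercept; exact collinearity is flagged infinite.  `vifstep`
iteratively removes the largest-VIF predictor above the threshold
(default 10) and reports the removal sequence and final values.

## Synthetic study system

The generator emulates an arid mountainous region at desk scale so every
stage has a known truth.  Defaults are the study conditions of the system
it models: 171 species, diurnal fraction 101/171, endemic fraction
62/171, about 50 raw records per species, six biomes, a 120×100 grid of
1-km cells with a 10× finer DEM.

One master seed feeds named sub-seeds (landscape, species, counts), so
stages can be regenerated independently and runs are bit-reproducible.
Smooth fields are low-order cosine mixtures (6 modes, 25–80 km
wavelengths) — deterministic, library-independent noise.  The DEM is a
sum of Gaussian massifs plus smooth noise; temperature = base +
latitudinal gradient + elevation lapse (−6.5 °C/km) + noise; the LGM
state is cooler by a spatially varying positive field (mean 5 °C) and
drier by one (mean 60 mm).  Precipitation carries its own east–west
aridity gradient and smooth field with a weaker orographic term, and
NDVI is a saturating function of precipitation plus its own noise: these
choices keep predictor collinearity low (VIFs in the low single digits
for most seeds), which is the regime the attribution method itself
assumes and reports.  Biomes are the Voronoi cells of random seed points
clipped to an elliptical study area; mountains are random ellipses with
uplift ages in 3–20 Myr.

Species draw a thermal niche interval (width 2–8 °C) and a 1–3 biome
subset; the true range is the cells of those biomes whose temperature
lies in the niche (resampled, with a log message, if empty).
Occurrences are sampled from true-range cells around 1–4 cluster centres
(Gaussian weights, σ = 6 km), mimicking aggregated field sampling, and
are placed at cell centres by default (`jitter_frac` adds within-cell
jitter) — so "occurrence in its own presence cell" is exact under
cell-centre rasterization.  Every occurrence lies inside its species'
true range by construction.

Ground-truth counts are Poisson draws from
log μ = β₀ + Σ βⱼ zⱼ on z-scored predictors, with the default β giving
temperature the dominant slope.  The z values are winsorized at ±5 for
the *generation* step only: climate velocity's heavy tail would otherwise
put astronomically large counts on a few near-flat cells.  A linear
predictor exceeding |50| is rejected outright.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: observation bias beyond simple clustering,
coordinate uncertainty, taxonomic error, spatial autocorrelation of
residual richness, realistic paleoclimate anomaly structure, and
phylogenetic structure among niches.  Conclusions about those require
real data and methods outside this package's scope.

## Pipeline sizes and determinism

The default test and acceptance runs use the 120×100 study system
(≈8 000 valid cells, 171 species) and a 60×50 variant for per-test
speed; these sizes give stable GLMs while keeping full runs in seconds.
Identical configuration and seed reproduce identical artifact checksums,
which the manifest records per output file.

## Known limitations

- Quasi-Poisson AIC is a convention, not a likelihood quantity; model
  ranking by it inherits that caveat.
- Cell-level fits ignore spatial autocorrelation; standard errors are
  anti-conservative on strongly autocorrelated richness surfaces.
- The hull range is an extent-of-occurrence proxy: it overfills concave
  or fragmented ranges and misses unsampled range parts; the temperature
  envelope only trims climatic outliers, it does not model the niche.
- Real-data mode expects pre-aligned rasters on one grid; there is no
  on-the-fly reprojection or resampling.
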