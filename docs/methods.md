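# Methods

## The model

Silvopasture — trees deliberately kept on pastureland — cools the local land
surface. With no before/after implementation record, the cooling is measured
cross-sectionally through the **forest equivalent temperature (FET)**:

    FET(pixel) = T(pixel) − T̄_forest(latitude of pixel)

where `T` is the annual-mean daytime land-surface temperature and
`T̄_forest(φ)` is the mean temperature of intact tropical/subtropical dry and
moist broadleaf forest at the same latitude. Subtracting a latitude-matched
forest baseline removes the continental-scale solar-radiation gradient;
FET = 0 means "as cool as intact forest", and the intact-forest pixels have
mean FET of exactly zero by construction.

FET is then related to woody carbon density `C` (aboveground woody biomass
× 0.47, tC/ha) by ordinary least squares over silvopasture pixels
(`C` > 5 tC/ha), giving a cooling coefficient `m` in °C per 10 tC/ha. The
same regression is run at patch level: contiguous (edge-connected) patches of
silvopasture pixels are found by flood fill, and mean within-patch FET is
regressed on log10(patch area) and, per size class (small < 10 km²,
medium 10–33, large 33–100, x-large > 100), on mean within-patch density.

The **action maps** apply the linear law ΔT = m·ΔC counterfactually: every
eligible pasture pixel below its biome's median silvopasture density is
raised to that median (ΔC = max(0, median − C)), the implied cooling
−ΔT = −(m/10)·ΔC is divided by the projected mid-century warming (late-
minus-early climatology raster), and the ratio is reported as a percentage.
Values above 100 % are kept in the data; clamping is a rendering choice.

## Pipeline assumptions and filters

- Pixels are treated as equal-area (nominal 1 km²); cos-latitude weighting is
  deliberately not applied so that area and carbon totals follow simple
  pixel-count accounting.
- Coverage rule: a pixel enters the analysis only if **more than** half of it
  is pasture (strict > 0.5).
- Biome exclusions: montane grasslands/shrublands, deserts/xeric shrublands,
  and mangroves are removed before any statistic.
- Density classes: ≤ 1 tC/ha (no/low), 1–5 (low), > 5 (silvopasture); values
  exactly on a class boundary go to the lower class, while patch areas
  exactly on a size-class boundary (10/33/100 km²) go to the larger class —
  in both cases the published inequalities are strict and leave the boundary
  unassigned, so a convention had to be fixed.
- Connectivity is 4-connected ("share at least one boundary" read as edge
  sharing; diagonal contact shares only a corner); 8-connectivity is a flag.
- Fine→coarse biomass aggregation is a pure block operation (integer nesting
  ratio, no interpolation): mean biomass over pasture cells of the block
  times the pasture fraction of the block. Fine cells with missing data are
  excluded from both the numerator and denominator of the block mean.
- The t-test for class comparisons is Welch's (unequal variances) — the
  conservative choice where the pooled/unpooled variant is unspecified.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| band_width | 0.25° | latitude-band width of the forest baseline; set to one grid row for exact per-row baselines |
| min_count | 30 | forest pixels a band needs before gap-filling (linear interpolation between populated bands, constant extrapolation at the ends) |
| carbon factor | 0.47 | biomass → carbon conversion, tC per t |
| density threshold | 5 tC/ha | silvopasture class bound, also the filter for biome medians |
| size-class bounds | 10/33/100 km² | patch classes |
| connectivity | 4 | patch adjacency rule |
| m | from pixel fit | scenario cooling coefficient, °C per 10 tC/ha; regional published values are config inputs, not code |

## The synthetic generator

Real inputs (satellite temperature, the pasture biomass layer, climate-model
warming) are large downloads; the generator builds landscapes with exactly
the statistical structure the analysis assumes, so each stage can be tested
by parameter recovery:

- forest belts are vertical (longitude) stripes so that **every** latitude
  band contains control pixels — this keeps baseline gap-filling out of
  recovery experiments;
- pasture pixels are `f(lat) + δ + (m/10)·C [+ s_area·log10 A] + N(0, σ²)`,
  forest pixels `f(lat) + N(0, σ²)`, with `f` a smooth polynomial profile,
  δ the warm offset of treeless pasture (default 2 °C), and optional
  per-size-class density slopes replacing the pixel-level law;
- patches are grown by uniformly-random 4-connected frontier accretion to
  log-normal target areas, each inside its own tile with a one-pixel gap
  (shelf packing), so planted patches are exactly the connected components
  the flood fill recovers; patch density is constant within a patch
  (log-normal across patches), background pasture density is log-normal with
  a low median (0.3 tC/ha);
- the warming field is a constant plus a linear latitude gradient;
  everything is reproducible from a single integer seed.

Presets plant the published regional estimates as ground truth:
`americas-default` / `africa-default` (pixel slopes −1.11 / −0.83 °C per
10 tC/ha; ≈ 50,000 silvopasture pixels from 1,260 patches, σ = 1.5 °C),
`patch-area-americas` / `patch-area-africa` (log-area slopes −0.79 / +0.29 °C
per decade; 1,500 patches with wide log-normal area spread, σ = 1.0 °C), and
`table1-africa-small` (small-class density slope −2.37; 400 patches < 10 km²,
σ = 1.0 °C). These sizes keep each recovery run to seconds while leaving the
slope standard error several times smaller than the recovery tolerances.

What the generator does **not** emulate: orography, coastlines, zonal
inhomogeneities, spatially correlated (regional) interannual variability,
retrieval error in the satellite products, or realistic patch shapes (the
patch analysis is deliberately shape-agnostic). Passing recovery tests
therefore shows the pipeline is an unbiased estimator under the assumed
model, not that the model captures every feature of the real rasters.

## Numerical choices

- OLS via `scipy.stats.linregress`; slopes on density are scaled ×10 to the
  °C-per-10-tC/ha reporting convention (intercepts unscaled). A constant
  regressor or n < 3 raises rather than returning a degenerate fit.
- Welch t on identical zero-variance groups returns p = 1 by convention.
- Patch labeling uses `scipy.ndimage.label` relabeled to row-major
  first-occurrence order, so labels are deterministic and match a
  breadth-first search exactly (the BFS lives in the test suite as an
  independent oracle).
- Quantiles are the linear-interpolation definition (numpy default).
- Noiseless validation runs use one-row latitude bands: with a smooth
  latitudinal profile and wide bands, within-band curvature of the profile
  leaks ~10⁻² °C into FET — harmless under noise, but row bands make the
  σ = 0 chain exact to machine precision.
- Grids compare equal within 1e-9° so a write→read round trip through the
  ASCII header leaves fields combinable.
- Patches whose pixels are all missing in the FET field are flagged and
  excluded from regressions; empty summary groups report n = 0.

## File formats

Rasters are ESRI ASCII grids (plain text, single band, regular lat/lon,
explicit nodata) with NetCDF accepted for warming fields; biome maps add a
JSON legend sidecar; tables are CSV; configs YAML; run manifests JSON.

## Known limitations

- Single-CRS (geographic lat/lon) only; no reprojection or QA/cloud-mask
  handling of real satellite granules.
- Equal-area pixel accounting over- or under-weights area by cos(latitude);
  acceptable in the tropics, increasingly wrong poleward.
- The scenario inherits the linearity and exogeneity of ΔT = m·ΔC; it is a
  counterfactual accounting device, not a land-surface model.
- Real-data headline quantities (regional mean cooling, GtC totals, country
  tables) require the real rasters and are out of scope; the tested claims
  are recovery of the regression structure.
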