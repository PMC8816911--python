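"""Synthetic landscape generator.

Builds gridded landscapes with the statistical structure the analysis
assumes, so every pipeline stage can be tested — and planted coefficients
recovered — without any satellite downloads:

* a smooth latitudinal temperature profile (polynomial in latitude),
* vertical intact-forest belts spanning all latitudes, so every latitude
  band has control pixels for the baseline,
* open pasture with a warm offset δ relative to forest,
* silvopasture patches grown by stochastic region-filling, with areas and
  densities drawn from log-normal distributions; patches are laid out in
  disjoint tiles separated by a one-pixel gap, so the generated patches are
  exactly the 4-connected components a flood fill recovers,
* linear cooling proportional to woody carbon density (m, °C per 10 tC/ha),
  an optional log10(area) patch-size effect, and optional per-size-class
  density slopes that override the pixel-level law,
* i.i.d. Gaussian pixel noise (interannual variability has no warm/cold
  bias), and a spatially smooth projected-warming field.

Presets plant the published regional regression estimates so that recovery
experiments measure the pipeline against known truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as _dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .biomes import (DEFAULT_LEGEND, TROPICAL_GRASSLANDS,
                     TROPICAL_MOIST_BROADLEAF, BiomeMap, write_biome_map)
from .grids import Field, GeoGrid, write_raster
from .patches import classify_patch_size


@dataclass
class LandscapeParams:
    """Everything that defines a synthetic landscape.

    ``baseline_profile`` holds polynomial coefficients (highest degree
    first, np.polyval convention) of the forest temperature as a function of
    latitude in °C.  Distributions are (log-mean, log-sd) of log-normals;
    ``patch_area_max`` optionally truncates patch areas (km², resampling).
    """

    grid: GeoGrid
    baseline_profile: tuple = (-0.05, 0.1, 29.0)   # °C as poly(lat)
    pasture_offset: float = 2.0                    # δ: FET of zero-carbon pasture, °C
    cooling_coeff: float = -1.11                   # m_true, °C per 10 tC/ha
    patch_area_log10_effect: float = 0.0           # s_area, °C per decade of area
    class_density_slopes: dict | None = None       # size_class → °C per 10 tC/ha
    noise_sd: float = 1.5                          # σ, °C
    n_patches: int = 1260
    patch_area_dist: tuple = (math.log(30.0), 0.75)   # km²
    patch_area_max: float | None = None
    patch_density_dist: tuple = (math.log(12.0), 0.5)  # tC/ha
    background_density_dist: tuple = (math.log(0.3), 0.5)
    forest_fraction: float = 1.0 / 6.0   # fraction of columns in forest belts
    warming_base: float = 2.0            # °C at the grid's mid latitude
    warming_lat_gradient: float = 0.1    # °C per degree latitude
    multi_biome: int = 1                 # pasture biomes, assigned by longitude band
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.forest_fraction < 1:
            raise ValueError("forest_fraction must be in (0, 1)")
        if self.n_patches < 0:
            raise ValueError("n_patches must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = self.grid.to_dict()
        return d


@dataclass
class LandscapeTruth:
    """Ground truth sufficient to verify recovery without re-derivation:
    the planted patch table, the planted coefficients, and the noiseless
    temperature field."""

    patches: pd.DataFrame          # patch_id, n_pixels, area_km2, density_tc_ha, size_class
    patch_id_raster: np.ndarray    # planted patch membership, 0 = background
    cooling_coeff: float
    patch_area_log10_effect: float
    pasture_offset: float
    noise_sd: float
    noiseless_temperature: Field


@dataclass
class Landscape:
    temperature: Field
    carbon: Field
    pasture_fraction: Field
    biomes: BiomeMap
    warming: Field
    truth: LandscapeTruth
    params: LandscapeParams


# ---------------------------------------------------------------------------
# Patch placement: shelf-packed tiles + stochastic region growing
# ---------------------------------------------------------------------------

def _grow_patch(r0: int, c0: int, side: int, target: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Grow a 4-connected patch of ``target`` pixels inside the box
    [r0, r0+side) × [c0, c0+side) by uniformly-random frontier accretion."""
    start = (r0 + side // 2, c0 + side // 2)
    chosen = {start}
    frontier: list[tuple[int, int]] = []
    in_frontier: set[tuple[int, int]] = set()

    def push_neighbors(cell):
        r, c = cell
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if (r0 <= rr < r0 + side and c0 <= cc < c0 + side
                    and (rr, cc) not in chosen and (rr, cc) not in in_frontier):
                frontier.append((rr, cc))
                in_frontier.add((rr, cc))

    push_neighbors(start)
    while len(chosen) < target:
        i = int(rng.integers(len(frontier)))
        cell = frontier[i]
        frontier[i] = frontier[-1]
        frontier.pop()
        in_frontier.discard(cell)
        chosen.add(cell)
        push_neighbors(cell)
    arr = np.array(sorted(chosen))
    return arr[:, 0], arr[:, 1]


def _place_patches(areas_px: np.ndarray, n_rows: int, col0: int, col1: int,
                   rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shelf-pack one tile per patch into the pasture block (rows 0..n_rows,
    cols col0..col1) and grow each patch inside its tile.  Tiles keep a
    one-pixel gap so patches are never mutually adjacent.  Returns member
    pixel indices per patch, in the original patch order."""
    sides = np.ceil(np.sqrt(areas_px)).astype(int)
    order = np.argsort(-sides, kind="stable")   # big tiles first packs tighter
    members: list = [None] * len(areas_px)
    r_shelf, c_cur, shelf_h = 0, col0, 0
    for i in order:
        tile = sides[i] + 1   # +1: gap to the right and below
        if c_cur + tile > col1:
            r_shelf += shelf_h
            c_cur, shelf_h = col0, 0
        if r_shelf + tile > n_rows:
            raise ValueError(
                f"requested patches exceed the pasture area: need more than "
                f"{n_rows}×{col1 - col0} pasture pixels")
        members[i] = _grow_patch(r_shelf, c_cur, sides[i], int(areas_px[i]), rng)
        c_cur += tile
        shelf_h = max(shelf_h, tile)
    return members


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_landscape(params: LandscapeParams) -> Landscape:
    """Generate temperature, carbon, pasture-fraction, biome, and warming
    fields plus the ground truth, fully reproducible from ``params.seed``."""
    g = params.grid
    rng = np.random.default_rng(params.seed)
    n_forest_cols = max(1, round(params.forest_fraction * g.n_cols))
    lat = g.lat_centers()
    lat2d = np.broadcast_to(lat[:, None], g.shape)
    f_lat = np.polyval(params.baseline_profile, lat2d)

    # --- carbon field and planted patches
    px_area = g.nominal_pixel_area
    areas_km2 = rng.lognormal(*params.patch_area_dist, size=params.n_patches)
    if params.patch_area_max is not None:
        # truncate by resampling, against the area after rounding to whole
        # pixels (what the patch actually occupies)
        for i in range(params.n_patches):
            while round(areas_km2[i] / px_area) * px_area >= params.patch_area_max:
                areas_km2[i] = rng.lognormal(*params.patch_area_dist)
    areas_px = np.maximum(1, np.round(areas_km2 / px_area).astype(int))
    densities = rng.lognormal(*params.patch_density_dist, size=params.n_patches)

    members = _place_patches(areas_px, g.n_rows, n_forest_cols, g.n_cols, rng)

    carbon = np.zeros(g.shape)
    patch_ids = np.zeros(g.shape, dtype=int)
    for pid, ((rr, cc), dens) in enumerate(zip(members, densities), start=1):
        carbon[rr, cc] = dens
        patch_ids[rr, cc] = pid

    pasture = np.zeros(g.shape, dtype=bool)
    pasture[:, n_forest_cols:] = True
    background = pasture & (patch_ids == 0)
    carbon[background] = rng.lognormal(*params.background_density_dist,
                                       size=int(background.sum()))

    # --- biomes: forest belt is moist broadleaf; pasture split by longitude
    legend = dict(DEFAULT_LEGEND)
    codes = np.zeros(g.shape, dtype=int)
    forest_code = {v: k for k, v in legend.items()}[TROPICAL_MOIST_BROADLEAF]
    codes[:, :n_forest_cols] = forest_code
    grass_code = {v: k for k, v in legend.items()}[TROPICAL_GRASSLANDS]
    if params.multi_biome <= 1:
        codes[:, n_forest_cols:] = grass_code
    else:
        edges = np.linspace(n_forest_cols, g.n_cols, params.multi_biome + 1).astype(int)
        next_code = max(legend) + 1
        for b in range(params.multi_biome):
            code = grass_code if b == 0 else next_code + b - 1
            if b > 0:
                legend[code] = f"{TROPICAL_GRASSLANDS} (zone {b + 1})"
            codes[:, edges[b]:edges[b + 1]] = code

    # --- noiseless temperature
    area_per_patch = areas_px * px_area
    t0 = f_lat.copy()
    t0[pasture] += params.pasture_offset
    if params.class_density_slopes:
        # per-class law: patch members cool by (s_class/10)·mean patch density
        for pid, ((rr, cc), dens, a) in enumerate(
                zip(members, densities, area_per_patch), start=1):
            s = params.class_density_slopes.get(classify_patch_size(a),
                                                params.cooling_coeff)
            t0[rr, cc] += (s / 10.0) * dens
        t0[background] += (params.cooling_coeff / 10.0) * carbon[background]
    else:
        t0[pasture] += (params.cooling_coeff / 10.0) * carbon[pasture]
    if params.patch_area_log10_effect:
        log_a = np.zeros(g.shape)
        for (rr, cc), a in zip(members, area_per_patch):
            log_a[rr, cc] = math.log10(a)
        t0 += params.patch_area_log10_effect * log_a

    temperature = t0 + (rng.normal(0.0, params.noise_sd, g.shape)
                        if params.noise_sd > 0 else 0.0)

    # --- warming field: smooth in latitude, positive
    mid = 0.5 * (g.lat_min + g.lat_max)
    warming = params.warming_base + params.warming_lat_gradient * (lat2d - mid)

    truth_patches = pd.DataFrame({
        "patch_id": np.arange(1, params.n_patches + 1),
        "n_pixels": areas_px,
        "area_km2": area_per_patch,
        "density_tc_ha": densities,
        "size_class": [classify_patch_size(a) for a in area_per_patch],
    })
    truth = LandscapeTruth(
        patches=truth_patches,
        patch_id_raster=patch_ids,
        cooling_coeff=params.cooling_coeff,
        patch_area_log10_effect=params.patch_area_log10_effect,
        pasture_offset=params.pasture_offset,
        noise_sd=params.noise_sd,
        noiseless_temperature=Field(g, t0, "°C"),
    )
    return Landscape(
        temperature=Field(g, np.asarray(temperature, dtype=float), "°C"),
        carbon=Field(g, carbon, "tC/ha"),
        pasture_fraction=Field(g, pasture.astype(float), "fraction"),
        biomes=BiomeMap(g, codes, legend),
        warming=Field(g, warming, "°C"),
        truth=truth,
        params=params,
    )


def write_landscape(ls: Landscape, outdir: str | Path) -> dict[str, str]:
    """Write all layers in the formats the pipeline reads, plus a manifest
    echoing the parameters and planted truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "temperature": "temperature.asc", "carbon": "carbon.asc",
        "pasture_fraction": "pasture_fraction.asc", "biomes": "biomes.asc",
        "legend": "biome_legend.json", "warming": "warming.asc",
        "truth_patches": "truth_patches.csv", "manifest": "manifest.json",
    }
    write_raster(ls.temperature, outdir / paths["temperature"])
    write_raster(ls.carbon, outdir / paths["carbon"])
    write_raster(ls.pasture_fraction, outdir / paths["pasture_fraction"])
    write_biome_map(ls.biomes, outdir / paths["biomes"], outdir / paths["legend"])
    write_raster(ls.warming, outdir / paths["warming"])
    ls.truth.patches.to_csv(outdir / paths["truth_patches"], index=False)
    manifest = {
        "params": ls.params.to_dict(),
        "truth": {
            "cooling_coeff": ls.truth.cooling_coeff,
            "patch_area_log10_effect": ls.truth.patch_area_log10_effect,
            "pasture_offset": ls.truth.pasture_offset,
            "noise_sd": ls.truth.noise_sd,
        },
        "files": paths,
    }
    with open(outdir / paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {k: str(outdir / v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Presets planting the published regional estimates
# ---------------------------------------------------------------------------

def _pixel_preset_grid() -> GeoGrid:
    # ~50k silvopasture pixels (1260 patches, log-normal mean ≈ 40 km²)
    return GeoGrid(origin_lat=10.0, origin_lon=-60.0, cell_size=0.01,
                   n_rows=400, n_cols=480)


def _patch_preset_grid() -> GeoGrid:
    return GeoGrid(origin_lat=10.0, origin_lon=20.0, cell_size=0.01,
                   n_rows=320, n_cols=400)


PRESETS: dict[str, dict] = {
    # Pixel-level slope recovery: 50k silvopasture pixels, σ = 1.5 °C.
    "americas-default": dict(grid=_pixel_preset_grid(), cooling_coeff=-1.11,
                             noise_sd=1.5, n_patches=1260,
                             patch_area_dist=(math.log(30.0), 0.75)),
    "africa-default": dict(grid=_pixel_preset_grid(), cooling_coeff=-0.83,
                           noise_sd=1.5, n_patches=1260,
                           patch_area_dist=(math.log(30.0), 0.75)),
    # Patch log-area slope recovery: 1500 patches with wide area spread, σ = 1 °C.
    "patch-area-americas": dict(grid=_patch_preset_grid(), cooling_coeff=-1.11,
                                patch_area_log10_effect=-0.79, noise_sd=1.0,
                                n_patches=1500,
                                patch_area_dist=(math.log(8.0), 1.1)),
    "patch-area-africa": dict(grid=_patch_preset_grid(), cooling_coeff=-0.83,
                              patch_area_log10_effect=0.29, noise_sd=1.0,
                              n_patches=1500,
                              patch_area_dist=(math.log(8.0), 1.1)),
    # Per-class density slope recovery: 400 small patches (< 10 km²), σ = 1 °C.
    "table1-africa-small": dict(grid=GeoGrid(origin_lat=10.0, origin_lon=20.0,
                                             cell_size=0.01, n_rows=160, n_cols=240),
                                cooling_coeff=0.0,
                                class_density_slopes={"small": -2.37},
                                noise_sd=1.0, n_patches=400,
                                patch_area_dist=(math.log(4.0), 0.5),
                                patch_area_max=10.0),
}


def preset(name: str, seed: int = 0, **overrides) -> LandscapeParams:
    """Named parameter sets whose planted coefficients equal the published
    regional estimates (pixel-level slopes, log-area slopes, small-class
    slope); any field can be overridden."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return LandscapeParams(seed=seed, **kwargs)
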