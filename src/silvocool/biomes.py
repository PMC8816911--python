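"""Categorical biome handling: exclusion masks, the intact-forest control set,
and per-biome silvopasture median densities.

Biome categories follow the standard terrestrial-ecoregion nomenclature.
Silvopasture on montane grasslands/shrublands and on deserts/xeric shrublands
is excluded (tree planting there is ecologically problematic), as are
mangroves (in-situ vs exported carbon accounting is intractable).  The
intact-forest control set — the reference against which forest equivalent
temperature is measured — is the union of the tropical/subtropical moist and
dry broadleaf forest categories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import DENSITY_CLASS_BOUNDS, Field, GeoGrid

TROPICAL_MOIST_BROADLEAF = "tropical/subtropical moist broadleaf forest"
TROPICAL_DRY_BROADLEAF = "tropical/subtropical dry broadleaf forest"
MONTANE_GRASSLANDS = "montane grasslands and shrublands"
DESERTS_XERIC = "deserts and xeric shrublands"
MANGROVES = "mangroves"
TROPICAL_GRASSLANDS = "tropical/subtropical grasslands, savannas and shrublands"

EXCLUDED_BIOMES = frozenset({MONTANE_GRASSLANDS, DESERTS_XERIC, MANGROVES})
FOREST_CONTROL_BIOMES = frozenset({TROPICAL_MOIST_BROADLEAF, TROPICAL_DRY_BROADLEAF})

DEFAULT_LEGEND: dict[int, str] = {
    1: TROPICAL_MOIST_BROADLEAF,
    2: TROPICAL_DRY_BROADLEAF,
    3: MONTANE_GRASSLANDS,
    4: DESERTS_XERIC,
    5: MANGROVES,
    6: TROPICAL_GRASSLANDS,
}

MISSING_CODE = -1


@dataclass
class BiomeMap:
    """Integer biome codes on a grid plus a legend mapping codes to canonical
    category names.  Code ``-1`` marks missing."""

    grid: GeoGrid
    codes: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.shape != self.grid.shape:
            raise ValueError("codes shape does not match grid")
        self.legend = {int(k): v for k, v in self.legend.items()}
        present = set(np.unique(self.codes[self.codes != MISSING_CODE]).tolist())
        unregistered = present - set(self.legend)
        if unregistered:
            raise ValueError(f"biome codes without legend entry: {sorted(unregistered)}")

    @property
    def missing(self) -> np.ndarray:
        return self.codes == MISSING_CODE

    def codes_field(self) -> Field:
        vals = np.where(self.missing, np.nan, self.codes.astype(float))
        return Field(self.grid, vals, "categorical", self.missing)

    def codes_for(self, names) -> list[int]:
        """Legend codes for the given category names; all must be registered."""
        by_name = {v: k for k, v in self.legend.items()}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise ValueError(f"legend is missing required categories: {missing}")
        return [by_name[n] for n in names]


def exclusion_mask(biomes: BiomeMap) -> np.ndarray:
    """True on pixels to drop: montane grasslands/shrublands, deserts and
    xeric shrublands, and mangroves."""
    codes = biomes.codes_for(sorted(EXCLUDED_BIOMES))
    return np.isin(biomes.codes, codes)


def forest_control_mask(biomes: BiomeMap) -> np.ndarray:
    """True on the intact-forest control set (tropical/subtropical dry or
    moist broadleaf forest)."""
    codes = biomes.codes_for(sorted(FOREST_CONTROL_BIOMES))
    return np.isin(biomes.codes, codes)


def biome_median_density(pixels: pd.DataFrame,
                         threshold: float = DENSITY_CLASS_BOUNDS[1]) -> dict[int, float]:
    """Per-biome median woody carbon density over silvopasture pixels only
    (carbon strictly above ``threshold`` tC/ha).  Biomes with no such pixels
    are absent from the result."""
    silvo = pixels[pixels["carbon_tc_ha"] > threshold]
    if silvo.empty:
        return {}
    med = silvo.groupby("biome")["carbon_tc_ha"].median()
    return {int(k): float(v) for k, v in med.items()}


# ---------------------------------------------------------------------------
# I/O: integer raster + JSON legend sidecar
# ---------------------------------------------------------------------------

def write_biome_map(biomes: BiomeMap, raster_path: str | Path,
                    legend_path: str | Path) -> None:
    from .grids import write_raster
    write_raster(biomes.codes_field(), raster_path, fmt="%d")
    with open(legend_path, "w") as fh:
        json.dump({str(k): v for k, v in biomes.legend.items()}, fh, indent=1)


def read_biome_map(raster_path: str | Path, legend_path: str | Path) -> BiomeMap:
    from .grids import read_raster
    field = read_raster(raster_path, "categorical")
    with open(legend_path) as fh:
        legend = {int(k): v for k, v in json.load(fh).items()}
    codes = np.where(field.missing, MISSING_CODE, field.values).astype(int)
    return BiomeMap(field.grid, codes, legend)
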