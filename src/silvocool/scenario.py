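"""Action maps: the biome-median intensification scenario.

The scenario raises every eligible pasture pixel whose woody carbon density
is below its biome's median silvopasture density (median over pixels with
> 5 tC/ha) up to that median, converts the added density ΔC into a
temperature change through the linear pixel-level relation

    ΔT = m · ΔC        (m in °C per tC/ha, negative = cooling)

and expresses the cooling as a percentage of the projected mid-century
warming at the same pixel.  m comes from the pixel-level fit — the
conservative choice, ignoring any additional benefit of large patches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomes import BiomeMap
from .grids import Field, require_same_grid

log = logging.getLogger(__name__)

HA_PER_KM2 = 100.0


def warming_anomaly(late_climatology: Field, early_climatology: Field) -> Field:
    """Projected warming: late minus early climatological temperature."""
    require_same_grid(late_climatology, early_climatology)
    vals = late_climatology.values - early_climatology.values
    missing = late_climatology.missing | early_climatology.missing
    return Field(late_climatology.grid, vals, "°C", missing)


def delta_c_to_median(carbon: Field, biomes: BiomeMap, medians: dict[int, float],
                      eligible_mask: np.ndarray) -> Field:
    """Carbon addition that lifts eligible below-median pixels to their biome
    median: ΔC = max(0, median(biome) − carbon); 0 elsewhere."""
    if carbon.grid != biomes.grid:
        raise ValueError("carbon and biome map are on different grids")
    eligible = np.asarray(eligible_mask, dtype=bool) & carbon.valid & ~biomes.missing
    codes = np.unique(biomes.codes[eligible])
    lacking = [int(c) for c in codes if int(c) not in medians]
    if lacking:
        names = [biomes.legend.get(c, "?") for c in lacking]
        raise ValueError(f"no silvopasture median for biomes {lacking} ({names})")
    target = np.zeros(carbon.grid.shape)
    for code in codes:
        target[biomes.codes == code] = medians[int(code)]
    delta = np.where(eligible, np.maximum(0.0, target - carbon.values), 0.0)
    return Field(carbon.grid, delta, "tC/ha")


def cooling_from_delta_c(delta_c: Field, m_per_10: float) -> Field:
    """ΔT = (m/10) ΔC with m in °C per 10 tC/ha (negative = cooling)."""
    if m_per_10 >= 0:
        warnings.warn(f"m = {m_per_10} °C per 10 tC/ha is non-negative: "
                      "this is a warming, not a cooling, scenario", stacklevel=2)
    return Field(delta_c.grid, (m_per_10 / 10.0) * delta_c.values, "°C",
                 delta_c.missing.copy())


def percent_counterbalanced(delta_t: Field, warming: Field) -> Field:
    """100 × (−ΔT) / warming.  Pixels with non-positive projected warming are
    flagged missing (count logged); values above 100 % are retained — any
    clamping is a rendering choice, not a data one."""
    require_same_grid(delta_t, warming)
    bad = (warming.values <= 0) & warming.valid & delta_t.valid
    n_bad = int(bad.sum())
    if n_bad:
        log.warning("percent_counterbalanced: %d pixels with non-positive "
                    "projected warming flagged missing", n_bad)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (-delta_t.values) / warming.values
    missing = delta_t.missing | warming.missing | bad
    return Field(delta_t.grid, np.where(missing, np.nan, pct), "%", missing)


def added_carbon_total(delta_c: Field, pixel_area_km2: float | None = None) -> dict[str, float]:
    """Total carbon added by the scenario.  ΔC (tC/ha) × 100 ha/km² × pixel
    area, summed over non-missing pixels; also in GtC."""
    if delta_c.units != "tC/ha":
        raise ValueError(f"expected ΔC in tC/ha, got {delta_c.units!r}")
    area = delta_c.grid.nominal_pixel_area if pixel_area_km2 is None else pixel_area_km2
    total = float(np.sum(delta_c.valid_values()) * HA_PER_KM2 * area)
    return {"total_tc": total, "total_gtc": total / 1e9}


@dataclass
class ScenarioMaps:
    """All per-pixel scenario fields plus the scalar summaries."""

    delta_c: Field
    delta_t: Field
    warming: Field
    percent_counterbalanced: Field
    total_added_carbon_tc: float
    total_added_carbon_gtc: float
    mean_cooling: float
    cooling_q25: float
    cooling_q75: float
    n_scenario_pixels: int

    def to_dict(self) -> dict:
        return {"total_added_carbon_tc": self.total_added_carbon_tc,
                "total_added_carbon_gtc": self.total_added_carbon_gtc,
                "mean_cooling_c": self.mean_cooling,
                "cooling_q25_c": self.cooling_q25,
                "cooling_q75_c": self.cooling_q75,
                "n_scenario_pixels": self.n_scenario_pixels}


def build_scenario(carbon: Field, biomes: BiomeMap, medians: dict[int, float],
                   eligible_mask: np.ndarray, warming: Field,
                   m_per_10: float) -> ScenarioMaps:
    """Compose the full action-map chain and its scalar summaries.  Scenario
    pixels are those actually intensified (ΔC > 0); cooling summaries are
    reported as positive magnitudes over them."""
    delta_c = delta_c_to_median(carbon, biomes, medians, eligible_mask)
    delta_t = cooling_from_delta_c(delta_c, m_per_10)
    pct = percent_counterbalanced(delta_t, warming)
    totals = added_carbon_total(delta_c)
    scen = delta_c.values > 0
    cooling = -delta_t.values[scen]
    if cooling.size:
        mean_c, q25, q75 = (float(cooling.mean()),
                            float(np.quantile(cooling, 0.25)),
                            float(np.quantile(cooling, 0.75)))
    else:
        mean_c = q25 = q75 = float("nan")
    return ScenarioMaps(delta_c, delta_t, warming, pct,
                        totals["total_tc"], totals["total_gtc"],
                        mean_c, q25, q75, int(scen.sum()))


def regional_summary(scenario: ScenarioMaps,
                     region_masks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-region scenario statistics over intensified pixels (ΔC > 0):
    mean/quartile cooling magnitude and added carbon.  Empty regions report
    n=0."""
    scen = scenario.delta_c.values > 0
    area = scenario.delta_c.grid.nominal_pixel_area
    rows = []
    for name, mask in region_masks.items():
        sel = scen & np.asarray(mask, dtype=bool)
        cooling = -scenario.delta_t.values[sel]
        gtc = float(scenario.delta_c.values[sel].sum() * HA_PER_KM2 * area / 1e9)
        if cooling.size:
            rows.append({"region": name, "n_pixels": int(sel.sum()),
                         "mean_cooling_c": float(cooling.mean()),
                         "q25": float(np.quantile(cooling, 0.25)),
                         "q75": float(np.quantile(cooling, 0.75)),
                         "added_carbon_gtc": gtc})
        else:
            rows.append({"region": name, "n_pixels": 0, "mean_cooling_c": np.nan,
                         "q25": np.nan, "q75": np.nan, "added_carbon_gtc": 0.0})
    return pd.DataFrame(rows)
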