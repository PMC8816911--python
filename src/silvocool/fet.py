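"""Forest equivalent temperature (FET).

FET is the pixel's annual-mean daytime surface temperature minus the mean
temperature of intact tropical/subtropical broadleaf forest at the same
latitude; 0 °C means "as cool as forest".  The latitudinal baseline removes
the continental-scale gradient in solar radiation, so that residual
temperature differences can be attributed to land cover.

This module fits the baseline, computes the FET field, summarises FET by
woody-carbon-density class, and runs the pixel-level regression and
group-comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .grids import DENSITY_CLASSES, Field, require_same_grid

DEFAULT_BAND_WIDTH = 0.25   # degrees latitude
DEFAULT_MIN_COUNT = 30      # forest pixels per band before gap-filling kicks in


@dataclass
class RegressionResult:
    """OLS fit summary.  ``slope`` is reported on the scale stated by the
    producing function (°C per 10 tC/ha for density fits, °C per log10 km²
    for patch-area fits)."""

    slope: float
    intercept: float
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a reported fit needs n ≥ 3")

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r": self.r, "p": self.p, "n": self.n}


def _ols(x: np.ndarray, y: np.ndarray, slope_scale: float = 1.0) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 points for a fit, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant regressor: slope is undefined")
    res = stats.linregress(x, y)
    return RegressionResult(slope=res.slope * slope_scale, intercept=res.intercept,
                            r=res.rvalue, p=res.pvalue, n=int(x.size))


@dataclass
class LatitudinalBaseline:
    """Mean intact-forest temperature in latitude bands.

    ``band_edges`` (length nb+1, ascending) partition the grid's latitude
    range; ``band_mean_temp`` may be NaN in unpopulated bands when gap-filling
    is disabled.
    """

    band_edges: np.ndarray
    band_mean_temp: np.ndarray
    band_n: np.ndarray

    def __post_init__(self) -> None:
        self.band_edges = np.asarray(self.band_edges, dtype=float)
        self.band_mean_temp = np.asarray(self.band_mean_temp, dtype=float)
        self.band_n = np.asarray(self.band_n, dtype=int)
        nb = self.band_edges.size - 1
        if nb < 1 or self.band_mean_temp.size != nb or self.band_n.size != nb:
            raise ValueError("inconsistent baseline arrays")
        if np.any(np.diff(self.band_edges) <= 0):
            raise ValueError("band edges must be strictly ascending")

    @property
    def n_bands(self) -> int:
        return self.band_edges.size - 1

    def band_index(self, lat: np.ndarray) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        if np.any(lat < self.band_edges[0] - 1e-9) or np.any(lat > self.band_edges[-1] + 1e-9):
            raise ValueError("latitude outside baseline coverage")
        idx = np.searchsorted(self.band_edges, lat, side="right") - 1
        return np.clip(idx, 0, self.n_bands - 1)

    def value_at(self, lat: np.ndarray) -> np.ndarray:
        return self.band_mean_temp[self.band_index(lat)]

    def band_centers(self) -> np.ndarray:
        return 0.5 * (self.band_edges[:-1] + self.band_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "band_lo": self.band_edges[:-1], "band_hi": self.band_edges[1:],
            "mean_temp_c": self.band_mean_temp, "n": self.band_n,
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def fit_baseline(temperature: Field, forest_mask: np.ndarray,
                 band_width: float = DEFAULT_BAND_WIDTH,
                 min_count: int = DEFAULT_MIN_COUNT,
                 gap_fill: bool = True) -> LatitudinalBaseline:
    """Per-band mean of intact-forest temperatures.

    Bands of ``band_width`` degrees partition the grid's latitude range
    (``band_width`` equal to the grid cell size gives per-row bands).  With
    ``gap_fill``, bands holding fewer than ``min_count`` forest pixels are
    filled by linear interpolation between populated bands and constant
    extrapolation at the ends; without it, any band with at least one forest
    pixel keeps its raw mean and empty bands stay NaN.
    """
    grid = temperature.grid
    forest_mask = np.asarray(forest_mask, dtype=bool)
    use = forest_mask & temperature.valid
    if not use.any():
        raise ValueError("no intact-forest pixels: cannot fit a baseline")

    lo, hi = grid.lat_min, grid.lat_max
    nb = max(1, int(np.ceil((hi - lo) / band_width - 1e-9)))
    edges = lo + np.arange(nb + 1) * band_width
    edges[-1] = max(edges[-1], hi)

    lat2d = np.broadcast_to(grid.lat_centers()[:, None], grid.shape)
    idx = np.clip(np.searchsorted(edges, lat2d[use], side="right") - 1, 0, nb - 1)
    n = np.bincount(idx, minlength=nb)
    sums = np.bincount(idx, weights=temperature.values[use], minlength=nb)
    with np.errstate(invalid="ignore"):
        means = np.where(n > 0, sums / np.maximum(n, 1), np.nan)

    if gap_fill:
        good = n >= min_count
        if not good.any():
            good = n > 0   # fall back to any populated band
        centers = 0.5 * (edges[:-1] + edges[1:])
        means = np.where(good, means,
                         np.interp(centers, centers[good], means[good]))
    return LatitudinalBaseline(edges, means, n)


def compute_fet(temperature: Field, baseline: LatitudinalBaseline) -> Field:
    """FET = temperature − latitudinal forest baseline; missing propagates.
    Pixels falling in a band with no baseline value (gap-fill disabled)
    become missing."""
    lat = temperature.grid.lat_centers()
    base_rows = baseline.value_at(lat)           # one baseline value per row
    fet = temperature.values - base_rows[:, None]
    missing = temperature.missing | ~np.isfinite(fet)
    return Field(temperature.grid, fet, "°C", missing)


def fet_summary(pixels: pd.DataFrame, by: str = "density_class") -> pd.DataFrame:
    """Per-group FET summary (n, mean, median, quartiles), groups in
    ascending density order.  Empty groups report n=0 and NaN statistics."""
    if by == "density_class":
        order = list(DENSITY_CLASSES)
    else:
        order = sorted(pixels[by].unique().tolist())
    rows = []
    grouped = dict(tuple(pixels.groupby(by, observed=True)))
    for name in order:
        vals = grouped[name]["fet_c"].to_numpy() if name in grouped else np.array([])
        vals = vals[np.isfinite(vals)]
        if vals.size:
            rows.append({"group": name, "n": vals.size, "mean": vals.mean(),
                         "median": float(np.median(vals)),
                         "q25": float(np.quantile(vals, 0.25)),
                         "q75": float(np.quantile(vals, 0.75))})
        else:
            rows.append({"group": name, "n": 0, "mean": np.nan, "median": np.nan,
                         "q25": np.nan, "q75": np.nan})
    return pd.DataFrame(rows)


def fit_fet_density(pixels: pd.DataFrame,
                    subset: str = "silvopasture") -> RegressionResult:
    """OLS of FET on woody carbon density over one density class
    (default: silvopasture, carbon > 5 tC/ha).  The slope is reported in
    °C per 10 tC/ha; p is the two-sided t-test on the slope."""
    sel = pixels if subset is None else pixels[pixels["density_class"] == subset]
    return _ols(sel["carbon_tc_ha"].to_numpy(), sel["fet_c"].to_numpy(),
                slope_scale=10.0)


def compare_groups(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """Two-sided Welch t-test.  Degenerate case (both groups constant with
    equal means) reports t=0, p=1 by convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need n ≥ 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return {"t": 0.0, "p": 1.0}
        return {"t": np.inf if a[0] > b[0] else -np.inf, "p": 0.0}
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p)}
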