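"""Grid/field data model, raster I/O, and fine→coarse biomass aggregation.

The whole pipeline works on rectangular latitude/longitude grids of nominally
1 km² pixels.  A :class:`GeoGrid` describes the grid geometry, a
:class:`Field` couples a grid with per-pixel values, units, and a missing-data
mask.  Fields are only combinable when their grids are identical.

Rasters are read and written as ESRI ASCII grids (``.asc`` — plain text,
regular lat/lon, single band, explicit nodata) or NetCDF (``.nc``) via xarray.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field
from pathlib import Path

import numpy as np
import pandas as pd

#: Aboveground woody biomass → woody carbon conversion factor (tC per t biomass).
CARBON_FRACTION = 0.47

#: Woody-carbon-density class boundaries, tC/ha.  Values at a boundary fall in
#: the lower class; the silvopasture class is strictly above the upper bound.
DENSITY_CLASS_BOUNDS = (1.0, 5.0)
DENSITY_CLASSES = ("no_low", "low", "silvopasture")

NODATA = -9999.0

PIXEL_TABLE_COLUMNS = [
    "row", "col", "lat", "lon", "temperature_c", "carbon_tc_ha",
    "pasture_fraction", "biome", "fet_c", "density_class",
]


@dataclass(frozen=True, eq=False)
class GeoGrid:
    """Regular lat/lon grid.  ``origin_lat``/``origin_lon`` are the
    latitude of the top edge and longitude of the left edge; rows run
    north→south, columns west→east."""

    origin_lat: float
    origin_lon: float
    cell_size: float        # degrees per pixel edge
    n_rows: int
    n_cols: int
    nominal_pixel_area: float = 1.0   # km²

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.nominal_pixel_area <= 0:
            raise ValueError("nominal_pixel_area must be positive")

    def __eq__(self, other: object) -> bool:
        # tolerant in the float members so that a write→read round trip
        # (origin re-derived from the file header) compares equal
        if not isinstance(other, GeoGrid):
            return NotImplemented
        return (self.n_rows == other.n_rows and self.n_cols == other.n_cols
                and math.isclose(self.origin_lat, other.origin_lat, abs_tol=1e-9)
                and math.isclose(self.origin_lon, other.origin_lon, abs_tol=1e-9)
                and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-9)
                and math.isclose(self.nominal_pixel_area, other.nominal_pixel_area,
                                 rel_tol=1e-9))

    def __hash__(self) -> int:
        return hash((self.n_rows, self.n_cols))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, north to south."""
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def lat_min(self) -> float:
        """Latitude of the grid's bottom edge."""
        return self.origin_lat - self.n_rows * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.origin_lat

    def to_dict(self) -> dict:
        return {
            "origin_lat": self.origin_lat, "origin_lon": self.origin_lon,
            "cell_size": self.cell_size, "n_rows": self.n_rows,
            "n_cols": self.n_cols, "nominal_pixel_area": self.nominal_pixel_area,
        }


VALID_UNITS = {"°C", "t/ha", "tC/ha", "fraction", "categorical", "%"}


@dataclass
class Field:
    """A gridded variable: values, units, and a boolean missing mask
    (True = missing).  Missing pixels are excluded from every statistic."""

    grid: GeoGrid
    values: np.ndarray
    units: str
    missing: np.ndarray = _dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}")
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {sorted(VALID_UNITS)}")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.grid.shape:
                raise ValueError("missing mask shape does not match grid")
            self.missing = self.missing | ~np.isfinite(self.values)
        if self.units == "fraction":
            ok = self.values[~self.missing]
            if ok.size and (ok.min() < 0 or ok.max() > 1):
                raise ValueError("fraction field has values outside [0, 1]")

    @property
    def valid(self) -> np.ndarray:
        return ~self.missing

    def valid_values(self) -> np.ndarray:
        return self.values[~self.missing]

    def with_values(self, values: np.ndarray, units: str | None = None,
                    missing: np.ndarray | None = None) -> "Field":
        return Field(self.grid, values, units or self.units,
                     self.missing.copy() if missing is None else missing)


def require_same_grid(*fields: Field | "object") -> GeoGrid:
    """All fields must share one grid; returns it."""
    grids = [f.grid for f in fields]  # type: ignore[attr-defined]
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise ValueError(f"fields are on different grids: {first} vs {g}")
    return first


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def write_raster(field: Field, path: str | Path, fmt: str = "%.10g") -> None:
    """Write a field as an ESRI ASCII grid (.asc) or NetCDF (.nc)."""
    path = Path(path)
    if path.suffix == ".nc":
        _write_netcdf(field, path)
        return
    g = field.grid
    vals = np.where(field.missing, NODATA, field.values)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_lon!r}\n"
        f"yllcorner {g.lat_min!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_raster(path: str | Path, expected_units: str) -> Field:
    """Read a single-band raster on a regular lat/lon grid.

    ``.asc`` files carry no unit metadata, so ``expected_units`` is assigned;
    NetCDF variables with a conflicting ``units`` attribute are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    if path.suffix == ".nc":
        return _read_netcdf(path, expected_units)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: body shape {vals.shape} disagrees with header "
                         f"({n_rows}, {n_cols})")
    cell = header["cellsize"]
    if cell <= 0:
        raise ValueError(f"{path}: non-positive cellsize — not a regular grid")
    grid = GeoGrid(origin_lat=header["yllcorner"] + n_rows * cell,
                   origin_lon=header["xllcorner"], cell_size=cell,
                   n_rows=n_rows, n_cols=n_cols)
    nodata = header.get("nodata_value", NODATA)
    missing = vals == nodata
    vals = np.where(missing, np.nan, vals)
    return Field(grid, vals, expected_units, missing)


def _write_netcdf(field: Field, path: Path) -> None:
    import xarray as xr
    g = field.grid
    vals = np.where(field.missing, np.nan, field.values)
    da = xr.DataArray(
        vals, dims=("lat", "lon"),
        coords={"lat": g.lat_centers(), "lon": g.lon_centers()},
        name="band1", attrs={"units": field.units},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def _read_netcdf(path: Path, expected_units: str) -> Field:
    import xarray as xr
    with xr.open_dataset(path, engine="scipy") as ds:
        names = [n for n in ds.data_vars if ds[n].ndim == 2]
        if len(names) != 1:
            raise ValueError(f"{path}: expected exactly one 2-D variable, found {names}")
        da = ds[names[0]].transpose("lat", "lon").load()
    units = da.attrs.get("units")
    if units is not None and units != expected_units:
        raise ValueError(f"{path}: units {units!r} do not match expected {expected_units!r}")
    lat = np.asarray(da["lat"]); lon = np.asarray(da["lon"])
    for coord, name in ((lat, "lat"), (lon, "lon")):
        step = np.diff(coord)
        if step.size and not np.allclose(step, step[0], rtol=1e-6):
            raise ValueError(f"{path}: irregular {name} spacing — not a regular grid")
    cell = abs(float(lat[1] - lat[0])) if lat.size > 1 else abs(float(lon[1] - lon[0]))
    vals = np.asarray(da, dtype=float)
    if lat.size > 1 and lat[1] > lat[0]:      # stored south→north: flip to north-up
        vals = vals[::-1]
        lat = lat[::-1]
    grid = GeoGrid(origin_lat=float(lat[0]) + cell / 2,
                   origin_lon=float(lon[0]) - cell / 2,
                   cell_size=cell, n_rows=lat.size, n_cols=lon.size)
    return Field(grid, vals, expected_units)


# ---------------------------------------------------------------------------
# Aggregation and conversions
# ---------------------------------------------------------------------------

def block_ratio(fine: GeoGrid, coarse: GeoGrid) -> int:
    """Integer block ratio by which ``fine`` nests into ``coarse``; raises if
    the grids do not nest exactly."""
    if fine.n_rows % coarse.n_rows or fine.n_cols % coarse.n_cols:
        raise ValueError(
            f"fine grid {fine.shape} does not nest into coarse {coarse.shape}")
    r = fine.n_rows // coarse.n_rows
    if fine.n_cols // coarse.n_cols != r:
        raise ValueError("row and column block ratios differ; grids do not nest")
    if not math.isclose(fine.cell_size * r, coarse.cell_size, rel_tol=1e-9):
        raise ValueError(
            f"cell sizes do not nest: {r} × {fine.cell_size}° ≠ {coarse.cell_size}°")
    if not (math.isclose(fine.origin_lat, coarse.origin_lat, abs_tol=1e-9)
            and math.isclose(fine.origin_lon, coarse.origin_lon, abs_tol=1e-9)):
        raise ValueError("fine and coarse grids have different origins")
    return r


def aggregate_biomass(fine_biomass: Field, fine_pasture_mask: Field,
                      coarse: GeoGrid) -> tuple[Field, Field]:
    """Regrid fine biomass to the analysis grid with pasture-fraction weighting.

    Per coarse pixel: mean biomass over the pasture cells of the block times
    the fraction of the block occupied by pasture — algebraically the block
    sum of pasture-masked biomass divided by the block cell count.  Fine cells
    with missing biomass or mask are excluded from both numerator and
    denominator of the mean; blocks with no pasture get biomass 0, fraction 0.
    """
    require_same_grid(fine_biomass, fine_pasture_mask)
    if fine_biomass.units != "t/ha":
        raise ValueError(f"expected biomass in t/ha, got {fine_biomass.units!r}")
    r = block_ratio(fine_biomass.grid, coarse)
    R, C = coarse.n_rows, coarse.n_cols

    is_pasture = ((fine_pasture_mask.values != 0)
                  & fine_pasture_mask.valid & fine_biomass.valid)
    blocks = lambda a: a.reshape(R, r, C, r)
    n_total = float(r * r)
    n_pasture = blocks(is_pasture).sum(axis=(1, 3)).astype(float)
    biomass_sum = blocks(np.where(is_pasture, fine_biomass.values, 0.0)).sum(axis=(1, 3))

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_on_pasture = np.where(n_pasture > 0, biomass_sum / np.maximum(n_pasture, 1), 0.0)
    frac = n_pasture / n_total
    pasture_biomass = mean_on_pasture * frac
    return (Field(coarse, pasture_biomass, "t/ha"),
            Field(coarse, frac, "fraction"))


def biomass_to_carbon(biomass: Field, factor: float = CARBON_FRACTION) -> Field:
    """Convert aboveground woody biomass (t/ha) to woody carbon density (tC/ha)."""
    if biomass.units != "t/ha":
        raise ValueError(f"expected units t/ha, got {biomass.units!r}")
    return Field(biomass.grid, biomass.values * factor, "tC/ha", biomass.missing.copy())


def coverage_mask(pasture_fraction: Field) -> np.ndarray:
    """True where more than half of the pixel is pasture (strict > 0.5);
    missing pixels are False."""
    if pasture_fraction.units != "fraction":
        raise ValueError(f"expected a fraction field, got {pasture_fraction.units!r}")
    return (pasture_fraction.values > 0.5) & pasture_fraction.valid


def classify_density(carbon_tc_ha: np.ndarray | float) -> np.ndarray:
    """Woody-carbon density class: ``no_low`` (≤1), ``low`` (1–5],
    ``silvopasture`` (>5 tC/ha).  Pure function of density."""
    c = np.asarray(carbon_tc_ha, dtype=float)
    lo, hi = DENSITY_CLASS_BOUNDS
    out = np.where(c > hi, DENSITY_CLASSES[2],
                   np.where(c > lo, DENSITY_CLASSES[1], DENSITY_CLASSES[0]))
    return out


def build_pixel_table(temperature: Field, carbon: Field, pasture_fraction: Field,
                      biome_codes: Field, fet: Field | None = None,
                      exclusion: np.ndarray | None = None) -> pd.DataFrame:
    """Assemble the per-pixel analysis table.

    Keeps only pixels that pass the coverage rule (> 50 % pasture), are not in
    an excluded biome (``exclusion`` True = excluded), and are non-missing in
    every input field.
    """
    grid = require_same_grid(temperature, carbon, pasture_fraction, biome_codes)
    keep = (coverage_mask(pasture_fraction) & temperature.valid
            & carbon.valid & biome_codes.valid)
    if exclusion is not None:
        keep &= ~np.asarray(exclusion, dtype=bool)
    if fet is not None:
        require_same_grid(temperature, fet)
        keep &= fet.valid
    rows, cols = np.nonzero(keep)
    lat = grid.lat_centers()[rows]
    lon = grid.lon_centers()[cols]
    carbon_vals = carbon.values[rows, cols]
    table = pd.DataFrame({
        "row": rows, "col": cols, "lat": lat, "lon": lon,
        "temperature_c": temperature.values[rows, cols],
        "carbon_tc_ha": carbon_vals,
        "pasture_fraction": pasture_fraction.values[rows, cols],
        "biome": biome_codes.values[rows, cols].astype(int),
        "fet_c": fet.values[rows, cols] if fet is not None else np.nan,
        "density_class": classify_density(carbon_vals),
    })
    return table[PIXEL_TABLE_COLUMNS]


def write_pixel_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_pixel_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
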