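"""Contiguous silvopasture patches: flood-fill labeling, per-patch statistics,
size classing, and the patch-level regressions.

A patch is a maximal set of silvopasture pixels that share at least one
boundary — edge adjacency (4-connectivity) by default, since diagonal contact
shares only a corner.  Patch area is pixel count × nominal pixel area, with
size classes small (<10 km²), medium (10–33), large (33–100) and x-large
(>100); areas exactly on a boundary go to the larger class.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .fet import RegressionResult, _ols
from .grids import Field, require_same_grid

SIZE_CLASS_BOUNDS = (10.0, 33.0, 100.0)   # km²
SIZE_CLASSES = ("small", "medium", "large", "x-large")

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
_STRUCTURE_8 = np.ones((3, 3), bool)


def label_patches(silvo_mask: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Label 4- (or, optionally, 8-) connected components of the silvopasture
    mask 1..K in row-major discovery order; background is 0."""
    mask = np.asarray(silvo_mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCTURE_4 if connectivity == 4 else _STRUCTURE_8
    labels, k = ndimage.label(mask, structure=structure)
    if k == 0:
        return labels
    # renumber by first row-major occurrence so labeling is deterministic
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    nz = uniq != 0
    order = np.argsort(first[nz])
    remap = np.zeros(k + 1, dtype=labels.dtype)
    remap[uniq[nz][order]] = np.arange(1, k + 1)
    return remap[labels]


def classify_patch_size(area_km2: float) -> str:
    """Size class of a patch area; boundary areas go to the larger class."""
    a = float(area_km2)
    if a <= 0:
        raise ValueError(f"patch area must be positive, got {a}")
    for bound, name in zip(SIZE_CLASS_BOUNDS, SIZE_CLASSES):
        if a < bound:
            return name
    return SIZE_CLASSES[-1]


def patch_stats(patch_ids: np.ndarray, fet: Field, carbon: Field) -> pd.DataFrame:
    """Per-patch area and unweighted means of FET and carbon density.

    Patches whose pixels are all missing in the FET field get NaN mean FET
    and ``fet_valid`` False; the regression helpers drop them.
    """
    require_same_grid(fet, carbon)
    patch_ids = np.asarray(patch_ids)
    if patch_ids.shape != fet.grid.shape:
        raise ValueError("patch id raster shape does not match grid")
    k = int(patch_ids.max())
    if k == 0:
        return pd.DataFrame(columns=["patch_id", "n_pixels", "area_km2", "mean_fet_c",
                                     "mean_carbon_tc_ha", "size_class", "fet_valid"])
    ids = patch_ids.ravel()
    member = ids > 0
    n_pixels = np.bincount(ids[member], minlength=k + 1)[1:]

    fet_ok = member & fet.valid.ravel()
    n_fet = np.bincount(ids[fet_ok], minlength=k + 1)[1:]
    fet_sum = np.bincount(ids[fet_ok], weights=fet.values.ravel()[fet_ok], minlength=k + 1)[1:]
    with np.errstate(invalid="ignore"):
        mean_fet = np.where(n_fet > 0, fet_sum / np.maximum(n_fet, 1), np.nan)

    carb_ok = member & carbon.valid.ravel()
    n_carb = np.bincount(ids[carb_ok], minlength=k + 1)[1:]
    carb_sum = np.bincount(ids[carb_ok], weights=carbon.values.ravel()[carb_ok], minlength=k + 1)[1:]
    with np.errstate(invalid="ignore"):
        mean_carb = np.where(n_carb > 0, carb_sum / np.maximum(n_carb, 1), np.nan)

    area = n_pixels * fet.grid.nominal_pixel_area
    return pd.DataFrame({
        "patch_id": np.arange(1, k + 1),
        "n_pixels": n_pixels,
        "area_km2": area,
        "mean_fet_c": mean_fet,
        "mean_carbon_tc_ha": mean_carb,
        "size_class": [classify_patch_size(a) for a in area],
        "fet_valid": n_fet > 0,
    })


def _fit_ready(patches: pd.DataFrame) -> pd.DataFrame:
    return patches[patches["fet_valid"] & np.isfinite(patches["mean_fet_c"])
                   & np.isfinite(patches["mean_carbon_tc_ha"])]


def fit_patch_area(patches: pd.DataFrame) -> RegressionResult:
    """OLS of mean within-patch FET on log10(area): the slope is the FET
    change per order-of-magnitude increase in contiguous patch area."""
    ready = _fit_ready(patches)
    return _ols(np.log10(ready["area_km2"].to_numpy()),
                ready["mean_fet_c"].to_numpy(), slope_scale=1.0)


def fit_patch_density_by_class(patches: pd.DataFrame) -> dict[str, RegressionResult]:
    """Per size class, OLS of mean within-patch FET on mean within-patch
    carbon density (°C per 10 tC/ha).  Classes with fewer than 3 usable
    patches (or constant density) are omitted; callers mark fits with
    p ≥ 0.001 as non-significant."""
    ready = _fit_ready(patches)
    out: dict[str, RegressionResult] = {}
    for name in SIZE_CLASSES:
        sub = ready[ready["size_class"] == name]
        if len(sub) < 3 or np.ptp(sub["mean_carbon_tc_ha"].to_numpy()) == 0:
            continue
        out[name] = _ols(sub["mean_carbon_tc_ha"].to_numpy(),
                         sub["mean_fet_c"].to_numpy(), slope_scale=10.0)
    return out


def write_patch_table(patches: pd.DataFrame, path: str | Path) -> None:
    cols = ["patch_id", "n_pixels", "area_km2", "mean_fet_c",
            "mean_carbon_tc_ha", "size_class"]
    patches[cols].to_csv(path, index=False)
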