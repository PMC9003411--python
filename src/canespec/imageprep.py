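"""Raster to grid-level samples: empirical-line radiometric
calibration, canopy masking, and ROI grid averaging.

Rasters are numpy arrays of shape (5, rows, cols) with fixed band
order B, G, R, RE, NIR; I/O goes through plain multiband TIFF
(float32 reflectance or uint16 digital numbers).  Mosaicking and
georeferencing are upstream of this module: ROIs are expressed in
pixel coordinates (0-based, half-open), so no CRS handling is needed.

Empirical-line calibration regresses known tarp reflectances (default
tarps: 5/20/40/60 %) on their mean image digital numbers, one ordinary
least-squares line per band, then maps every pixel DN to reflectance.

Canopy masking replaces an interactively trained decision-tree with a
reproducible two-rule threshold classifier: a pixel is canopy iff
NDVI exceeds a threshold (soil, concrete, water drop out) and its
summed 5-band reflectance exceeds a brightness floor (shadow drops
out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import stats

from .synthetic import BANDS

DEFAULT_TARP_REFLECTANCES = (0.05, 0.20, 0.40, 0.60)
DEFAULT_NDVI_THRESHOLD = 0.4
DEFAULT_SHADOW_FLOOR = 0.15  # summed 5-band reflectance


def read_raster(path) -> np.ndarray:
    """Load a 5-band TIFF as float (bands, rows, cols)."""
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == len(BANDS) and arr.shape[0] != len(BANDS):
        arr = np.moveaxis(arr, -1, 0)  # pixel-interleaved -> band-major
    if arr.ndim != 3 or arr.shape[0] != len(BANDS):
        raise ValueError(f"expected a 5-band raster, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_raster(path, raster: np.ndarray, dtype=np.float32) -> None:
    tifffile.imwrite(path, np.asarray(raster, dtype=dtype))


@dataclass(frozen=True)
class CalibrationLine:
    """Per-band OLS line mapping digital number to reflectance."""

    band: str
    slope: float  # reflectance per DN
    intercept: float  # reflectance
    r_squared: float
    n_tarps: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError(f"band {self.band}: non-finite calibration slope")
        if self.n_tarps < 2:
            raise ValueError("calibration requires >= 2 tarps")


def fit_empirical_line(
    tarp_dns: dict[str, np.ndarray] | pd.DataFrame,
    tarp_reflectances: np.ndarray = DEFAULT_TARP_REFLECTANCES,
) -> dict[str, CalibrationLine]:
    """Fit one DN -> reflectance line per band from calibration tarps.

    `tarp_dns` maps band name to the mean DN of each tarp, or is a
    table with columns dn_B..dn_NIR (one row per tarp).  All tarps
    sharing one DN in a band makes that band's fit degenerate and
    raises.
    """
    if isinstance(tarp_dns, pd.DataFrame):
        if "reflectance" in tarp_dns.columns:
            tarp_reflectances = tarp_dns["reflectance"].to_numpy(float)
        tarp_dns = {b: tarp_dns[f"dn_{b}"].to_numpy(float) for b in BANDS}
    rho = np.asarray(tarp_reflectances, float)
    if len(rho) < 2:
        raise ValueError("need at least 2 tarps")
    lines = {}
    for b in BANDS:
        dn = np.asarray(tarp_dns[b], float)
        if dn.shape != rho.shape:
            raise ValueError(f"band {b}: {len(dn)} DNs for {len(rho)} tarp reflectances")
        if np.ptp(dn) == 0:
            raise ValueError(f"band {b}: identical DN for all tarps, degenerate fit")
        if len(dn) == 2:
            slope = (rho[1] - rho[0]) / (dn[1] - dn[0])
            lines[b] = CalibrationLine(b, float(slope), float(rho[0] - slope * dn[0]), 1.0, 2)
        else:
            res = stats.linregress(dn, rho)
            lines[b] = CalibrationLine(
                b, float(res.slope), float(res.intercept), float(res.rvalue**2), len(dn)
            )
    return lines


def apply_calibration(
    dn_raster: np.ndarray, lines: dict[str, CalibrationLine]
) -> np.ndarray:
    """Per-pixel linear DN -> reflectance transform, clipped to [0, 1].

    NaN (no-data) pixels propagate unchanged.
    """
    missing = [b for b in BANDS if b not in lines]
    if missing:
        raise ValueError(f"missing calibration line(s) for band(s) {missing}")
    dn = np.asarray(dn_raster, float)
    if dn.shape[0] != len(BANDS):
        raise ValueError(f"raster has {dn.shape[0]} bands, expected {len(BANDS)}")
    out = np.empty_like(dn)
    for i, b in enumerate(BANDS):
        out[i] = np.clip(lines[b].slope * dn[i] + lines[b].intercept, 0.0, 1.0)
    out[np.isnan(dn)] = np.nan
    return out


@dataclass(frozen=True)
class CanopyMask:
    """Boolean raster: True where the pixel is sugarcane canopy."""

    mask: np.ndarray
    ndvi_threshold: float
    shadow_brightness_floor: float | None

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")


def mask_canopy(
    reflectance: np.ndarray,
    ndvi_threshold: float = DEFAULT_NDVI_THRESHOLD,
    shadow_brightness_floor: float | None = DEFAULT_SHADOW_FLOOR,
) -> CanopyMask:
    """Keep pixels with NDVI > threshold and (optionally) summed
    reflectance above the shadow brightness floor."""
    refl = np.asarray(reflectance, float)
    r = refl[BANDS.index("R")]
    nir = refl[BANDS.index("NIR")]
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = (nir - r) / (nir + r)
    keep = ndvi > ndvi_threshold
    if shadow_brightness_floor is not None:
        keep &= np.nansum(refl, axis=0) > shadow_brightness_floor
    keep &= ~np.isnan(refl).any(axis=0)
    return CanopyMask(keep, ndvi_threshold, shadow_brightness_floor)


@dataclass(frozen=True)
class AreaROI:
    """One sampling area: half-open pixel bounds [row0,row1) x [col0,col1)."""

    area_id: str
    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if not (0 <= self.row0 < self.row1 and 0 <= self.col0 < self.col1):
            raise ValueError(f"area {self.area_id}: invalid bounds")


@dataclass(frozen=True)
class GridSpec:
    """Sampling areas plus their sub-grid subdivision (default 3x3 = 9
    grids per area)."""

    areas: tuple[AreaROI, ...]
    grid_rows: int = 3
    grid_cols: int = 3

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("subdivision counts must be >= 1")

    def validate_against(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        for a in self.areas:
            if a.row1 > rows or a.col1 > cols:
                raise ValueError(f"area {a.area_id} exceeds raster shape {shape}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "grid_rows": self.grid_rows,
                "grid_cols": self.grid_cols,
                "areas": [
                    {"area_id": a.area_id, "row0": a.row0, "row1": a.row1,
                     "col0": a.col0, "col1": a.col1}
                    for a in self.areas
                ],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "GridSpec":
        d = yaml.safe_load(text)
        return cls(
            tuple(AreaROI(**a) for a in d["areas"]),
            d.get("grid_rows", 3),
            d.get("grid_cols", 3),
        )


def _edges(lo: int, hi: int, parts: int) -> np.ndarray:
    return np.linspace(lo, hi, parts + 1).round().astype(int)


def extract_grid_means(
    reflectance: np.ndarray,
    mask: CanopyMask,
    grids: GridSpec,
) -> pd.DataFrame:
    """Mean canopy reflectance per sub-grid of every sampling area.

    Returns one record per grid (row-major by area order, then grid
    row, then grid column) with columns area, grid, refl_B..refl_NIR,
    n_pixels, valid.  A grid with no canopy pixels is kept with NaN
    reflectance and valid=False — flagged, never silently dropped.
    """
    refl = np.asarray(reflectance, float)
    if refl.shape[1:] != mask.mask.shape:
        raise ValueError("mask shape does not match raster")
    grids.validate_against(mask.mask.shape)
    records = []
    for area in grids.areas:
        re_ = _edges(area.row0, area.row1, grids.grid_rows)
        ce = _edges(area.col0, area.col1, grids.grid_cols)
        gidx = 0
        for i in range(grids.grid_rows):
            for j in range(grids.grid_cols):
                sub = (slice(re_[i], re_[i + 1]), slice(ce[j], ce[j + 1]))
                m = mask.mask[sub]
                n_pix = int(m.sum())
                rec = {"area": area.area_id, "grid": gidx, "n_pixels": n_pix,
                       "valid": n_pix > 0}
                for bi, b in enumerate(BANDS):
                    vals = refl[bi][sub][m]
                    rec[f"refl_{b}"] = float(vals.mean()) if n_pix else np.nan
                records.append(rec)
                gidx += 1
    return pd.DataFrame(records)
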