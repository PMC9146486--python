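"""Volume standardization: fovea localization, 6x6 mm crop, resize.

The foveal A-scan is found by fitting a parabola to the inner-surface
height in the central half of each B-scan and taking the deepest fitted
vertex; the crop is centered on it laterally and across B-scans. The full
axial range is kept (the retina occupies a small fraction of it) and each
cropped B-scan is resized to the network input size with bilinear
interpolation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .types import BScanImage, FormatError, OCTVolume, QualityError, SurfaceSet

__all__ = [
    "PreprocessTransform",
    "estimate_inner_surface",
    "locate_fovea",
    "crop_and_resize",
    "preprocess_volume",
]

logger = logging.getLogger(__name__)


@dataclass
class PreprocessTransform:
    """Mapping between source pixel coordinates and preprocessed coordinates."""

    crop_rows: tuple[int, int]  # (first, last+1) in source rows
    crop_cols: tuple[int, int]  # (first, last+1) in source cols
    bscan_range: tuple[int, int]  # (first, last+1) source B-scan indices
    out_size: tuple[int, int]
    source_shape: tuple[int, int]
    clamped: bool = False

    @property
    def resize_factors(self) -> tuple[float, float]:
        rows = self.crop_rows[1] - self.crop_rows[0]
        cols = self.crop_cols[1] - self.crop_cols[0]
        return (self.out_size[0] / rows, self.out_size[1] / cols)

    def map_rows_cols(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Source pixel coordinates -> preprocessed coordinates (pixel centers)."""
        fr, fc = self.resize_factors
        out_r = (np.asarray(rows) - self.crop_rows[0] + 0.5) * fr - 0.5
        out_c = (np.asarray(cols) - self.crop_cols[0] + 0.5) * fc - 0.5
        return out_r, out_c

    def invert_rows_cols(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fr, fc = self.resize_factors
        src_r = (np.asarray(rows) + 0.5) / fr - 0.5 + self.crop_rows[0]
        src_c = (np.asarray(cols) + 0.5) / fc - 0.5 + self.crop_cols[0]
        return src_r, src_c

    def _resample(self, surfaces: SurfaceSet, src_cols: np.ndarray, rows_fwd: bool) -> np.ndarray:
        """Linear resample of every (boundary, bscan) row at fractional columns."""
        nb = surfaces.values.shape[1]
        na = surfaces.values.shape[2]
        grid = np.arange(na, dtype=np.float64)
        out = np.empty((surfaces.values.shape[0], nb, len(src_cols)))
        for k in range(out.shape[0]):
            for b in range(nb):
                out[k, b] = np.interp(src_cols, grid, surfaces.values[k, b])
        return out

    def apply_to_surfaces(self, surfaces: SurfaceSet) -> SurfaceSet:
        """Map surfaces (source grid) onto the preprocessed (resized) grid."""
        fr, fc = self.resize_factors
        out_h, out_w = self.out_size
        src_cols = (np.arange(out_w) + 0.5) / fc - 0.5 + self.crop_cols[0]
        sub = SurfaceSet(
            surfaces.values[:, self.bscan_range[0] : self.bscan_range[1], :],
            axial_scale=surfaces.axial_scale,
        )
        vals = self._resample(sub, np.clip(src_cols, 0, sub.values.shape[2] - 1), True)
        rows = (vals - self.crop_rows[0] + 0.5) * fr - 0.5
        return SurfaceSet(rows, axial_scale=surfaces.axial_scale / fr)

    def invert_surfaces(self, surfaces: SurfaceSet) -> SurfaceSet:
        """Map surfaces on the preprocessed grid back to source coordinates."""
        fr, fc = self.resize_factors
        na_src = self.crop_cols[1] - self.crop_cols[0]
        out_cols = (np.arange(self.crop_cols[0], self.crop_cols[1]) - self.crop_cols[0] + 0.5) * fc - 0.5
        sub = SurfaceSet(surfaces.values, axial_scale=surfaces.axial_scale)
        vals = self._resample(sub, np.clip(out_cols, 0, surfaces.values.shape[2] - 1), False)
        rows = (vals + 0.5) / fr - 0.5 + self.crop_rows[0]
        return SurfaceSet(rows, axial_scale=surfaces.axial_scale * fr)


def estimate_inner_surface(bscan: BScanImage, median_size: tuple[int, int] = (3, 3)) -> np.ndarray:
    """Per-column row index of the first bright pixel (NaN where none).

    Bright means the median-filtered intensity exceeds an Otsu threshold
    computed over the whole B-scan.
    """
    img = np.asarray(bscan.pixels, dtype=np.float64)
    med = ndimage.median_filter(img, size=median_size)
    if np.ptp(med) == 0:  # blank image: no threshold exists
        return np.full(img.shape[1], np.nan)
    thr = threshold_otsu(med)
    above = med > thr
    first = above.argmax(axis=0).astype(np.float64)
    first[~above.any(axis=0)] = np.nan
    return first


def _fit_parabola(cols: np.ndarray, rows: np.ndarray) -> Optional[tuple[float, float]]:
    """Least-squares parabola fit; returns (vertex_col, vertex_row) for a pit.

    In row coordinates a foveal pit is a *maximum* of the surface row, i.e.
    a downward-opening parabola (negative quadratic coefficient). Returns
    None when the fit opens the wrong way or is degenerate.
    """
    if len(cols) < 3:
        return None
    a, b, c = np.polyfit(cols, rows, 2)
    if a >= 0:
        return None
    vx = -b / (2 * a)
    return float(vx), float(np.polyval([a, b, c], vx))


def locate_fovea(surface_grid: np.ndarray) -> tuple[int, int, bool]:
    """Locate the fovea from a (n_bscans, n_ascans) inner-surface grid.

    Returns (bscan index, ascan index, used_fallback). The foveal B-scan is
    the one whose fitted parabola vertex is deepest (largest row); the
    foveal A-scan is that vertex, clamped to the central window. When no
    B-scan yields a pit-shaped fit, falls back to the location of the
    deepest grid sample and flags it.
    """
    grid = np.asarray(surface_grid, dtype=np.float64)
    nb, na = grid.shape
    lo, hi = na // 4, na - na // 4  # central half of the columns
    central = grid[:, lo:hi]
    if np.isnan(central).mean() >= 0.5:
        raise QualityError("more than 50% of the central inner-surface samples are missing")

    best: Optional[tuple[float, int, int]] = None
    cols = np.arange(lo, hi, dtype=np.float64)
    for b in range(nb):
        rows = grid[b, lo:hi]
        ok = np.isfinite(rows)
        fit = _fit_parabola(cols[ok], rows[ok]) if ok.sum() >= 3 else None
        if fit is None:
            continue
        vx, vy = fit
        vx = float(np.clip(vx, lo, hi - 1))
        if best is None or vy > best[0]:
            best = (vy, b, int(round(vx)))
    if best is not None:
        return best[1], best[2], False

    # no pit-shaped fit anywhere: deepest sample of the grid
    masked = np.where(np.isfinite(grid), grid, -np.inf)
    b, a = np.unravel_index(np.argmax(masked), grid.shape)
    logger.warning("fovea parabola fit failed; falling back to deepest grid sample")
    return int(b), int(a), True


def inner_surface_grid(volume: OCTVolume) -> np.ndarray:
    return np.stack([estimate_inner_surface(b) for b in volume.bscans])


def crop_and_resize(
    volume: OCTVolume,
    center: tuple[int, int],
    extent_mm: float = 6.0,
    out_size: tuple[int, int] = (512, 512),
) -> tuple[OCTVolume, PreprocessTransform]:
    """Crop an extent_mm-wide region around the foveal center and resize.

    The lateral crop width is ``round(extent_mm * 1000 / lateral_scale)``
    pixels centered on the foveal A-scan; the B-scan subset spans the same
    extent across slices; the full axial range is kept. Out-of-bounds crops
    are clamped (and flagged on the transform).
    """
    if volume.lateral_scale <= 0 or volume.bscan_spacing <= 0:
        raise FormatError("volume is missing positive lateral scales")
    nb, h, w = volume.shape
    fb, fa = center

    crop_w = int(round(extent_mm * 1000.0 / volume.lateral_scale))
    crop_w = min(crop_w, w)
    c0 = fa - crop_w // 2
    clamped = False
    if c0 < 0 or c0 + crop_w > w:
        c0 = int(np.clip(c0, 0, w - crop_w))
        clamped = True

    n_keep = int(round(extent_mm * 1000.0 / volume.bscan_spacing))
    n_keep = max(1, min(n_keep, nb))
    b0 = fb - n_keep // 2
    if b0 < 0 or b0 + n_keep > nb:
        b0 = int(np.clip(b0, 0, nb - n_keep))
        clamped = True

    tf = PreprocessTransform(
        crop_rows=(0, h),
        crop_cols=(c0, c0 + crop_w),
        bscan_range=(b0, b0 + n_keep),
        out_size=out_size,
        source_shape=(h, w),
        clamped=clamped,
    )
    fr, fc = tf.resize_factors
    out_bscans = []
    for b in range(b0, b0 + n_keep):
        crop = volume.bscans[b].pixels[:, c0 : c0 + crop_w]
        resized = resize(crop, out_size, order=1, mode="edge", anti_aliasing=False,
                         preserve_range=True)
        out_bscans.append(BScanImage(np.clip(resized, 0.0, 1.0)))
    out = OCTVolume(
        bscans=out_bscans,
        axial_scale=volume.axial_scale / fr,
        lateral_scale=volume.lateral_scale / fc,
        bscan_spacing=volume.bscan_spacing,
        fovea=(fb - b0, int(round((fa - c0) * fc))),
        volume_id=volume.volume_id,
    )
    return out, tf


def preprocess_volume(
    volume: OCTVolume,
    extent_mm: float = 6.0,
    out_size: tuple[int, int] = (512, 512),
    quality_gate: Optional[Callable[[OCTVolume], bool]] = None,
) -> tuple[OCTVolume, PreprocessTransform]:
    """Full preprocessing: quality gate, fovea localization, crop and resize.

    ``quality_gate`` is a user predicate standing in for an external
    quality-control system; the default accepts every volume.
    """
    if quality_gate is not None and not quality_gate(volume):
        raise QualityError(f"volume {volume.volume_id} rejected by the quality gate")
    grid = inner_surface_grid(volume)
    fb, fa, fallback = locate_fovea(grid)
    logger.info("fovea estimate: bscan=%d ascan=%d fallback=%s", fb, fa, fallback)
    return crop_and_resize(volume, (fb, fa), extent_mm=extent_mm, out_size=out_size)
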