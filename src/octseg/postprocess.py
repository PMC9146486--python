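"""From 9-class maps to clean, ordered boundary surfaces.

Chain: adaptive hole filling on the class maps, column-wise boundary
extraction, Laplacian-of-thickness outlier rejection, PCHIP infill of
missing samples, 3x3 box smoothing over the (B-scan, A-scan) grid, and a
final top-down ordering projection.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator
from skimage.measure import label as cc_label

from .types import BOUNDARY_NAMES, N_BOUNDARIES, SurfaceSet

__all__ = [
    "HoleFillConfig",
    "adaptive_threshold",
    "fill_holes",
    "extract_surfaces",
    "surfaces_from_maps",
    "remove_outliers",
    "interpolate_missing",
    "smooth_surfaces",
    "enforce_ordering",
    "postprocess_maps",
]


@dataclass(frozen=True)
class HoleFillConfig:
    f0_outer: int = 2  # start divisor for the first and last class
    f0_inner: int = 10  # start divisor for interior classes
    connectivity: int = 2  # skimage connectivity 2 == 8-connected

    def __post_init__(self) -> None:
        if self.f0_outer < 1 or self.f0_inner < 1:
            raise ValueError("hole-fill divisors must be >= 1")


def adaptive_threshold(binary_image: np.ndarray, f0: int) -> float:
    """Area threshold n_n / f with the smallest integer f >= f0 s.t. n_n/f < n_z."""
    mask = np.asarray(binary_image).astype(bool)
    n_n = int(mask.sum())
    n_z = mask.size - n_n
    if n_n == 0 or n_z == 0:  # nothing to threshold against
        return 0.0
    f = int(f0)
    while n_n / f >= n_z:
        f += 1
    return n_n / f


def _majority_border_label(classmap: np.ndarray, component: np.ndarray) -> int:
    """Most frequent label among the pixels bordering a component."""
    border = ndimage.binary_dilation(component, structure=np.ones((3, 3))) & ~component
    labels = classmap[border]
    if labels.size == 0:
        return int(classmap.max())
    vals, counts = np.unique(labels, return_counts=True)
    return int(vals[np.argmax(counts)])


def fill_holes(classmap: np.ndarray, cfg: HoleFillConfig | None = None) -> np.ndarray:
    """Remove small holes and islands per class with adaptive area thresholds.

    For each class mask, background-connected components smaller than the
    class threshold are filled into the class; foreground components smaller
    than the threshold are reassigned to the majority label of their border
    neighborhood (the map stays a partition).
    """
    cfg = cfg or HoleFillConfig()
    cm = np.asarray(classmap).copy()
    k_max = int(cm.max())
    for k in range(1, k_max + 1):
        mask = cm == k
        if not mask.any():
            continue
        f0 = cfg.f0_outer if k in (1, k_max) else cfg.f0_inner
        t = adaptive_threshold(mask, f0)
        if t <= 0:
            continue
        # fill small background holes into class k
        bg_labels, n_bg = cc_label(~mask, connectivity=cfg.connectivity, return_num=True)
        if n_bg:
            areas = np.bincount(bg_labels.ravel())
            for comp in range(1, n_bg + 1):
                if areas[comp] < t:
                    cm[bg_labels == comp] = k
        # remove small foreground islands
        mask = cm == k
        fg_labels, n_fg = cc_label(mask, connectivity=cfg.connectivity, return_num=True)
        if n_fg > 1 or (n_fg == 1 and (np.bincount(fg_labels.ravel())[1:] < t).any()):
            areas = np.bincount(fg_labels.ravel())
            for comp in range(1, n_fg + 1):
                if areas[comp] < t:
                    component = fg_labels == comp
                    cm[component] = _majority_border_label(cm, component)
    return cm


def extract_surfaces(classmap9: np.ndarray, axial_scale: float = 1.0) -> np.ndarray:
    """Per-column topmost row of each of regions 2..9 -> boundaries 1..8.

    Returns an (8, n_ascans) array with NaN where a region is absent from a
    column. (Boundary k is the top of region k+1: region 2's top edge is the
    ILM, ..., region 9's top edge is BM.)
    """
    cm = np.asarray(classmap9)
    h, w = cm.shape
    out = np.full((N_BOUNDARIES, w), np.nan)
    for k in range(N_BOUNDARIES):
        region = cm == k + 2
        has = region.any(axis=0)
        first = region.argmax(axis=0).astype(np.float64)
        out[k, has] = first[has]
        out[k, ~has] = np.nan
    return out


def surfaces_from_maps(classmaps: list[np.ndarray], axial_scale: float) -> SurfaceSet:
    """Stack per-B-scan boundary extractions into a volume SurfaceSet."""
    vals = np.stack([extract_surfaces(cm) for cm in classmaps], axis=1)
    return SurfaceSet(vals, axial_scale=axial_scale)


def _masked_laplacian(t: np.ndarray) -> np.ndarray:
    """Discrete Laplacian over the (bscan, ascan) grid, NaN-aware.

    Uses every available 4-neighbor: lap = sum(neighbor - center). Samples
    whose full stencil is missing yield NaN.
    """
    nb, na = t.shape
    lap = np.zeros_like(t)
    count = np.zeros_like(t)
    for shift, axis in (((1, 0), 0), ((-1, 0), 0), ((0, 1), 1), ((0, -1), 1)):
        rolled = np.full_like(t, np.nan)
        if shift[axis] == 1:
            sl_dst = [slice(None)] * 2
            sl_src = [slice(None)] * 2
            sl_dst[axis] = slice(1, None)
            sl_src[axis] = slice(None, -1)
        else:
            sl_dst = [slice(None)] * 2
            sl_src = [slice(None)] * 2
            sl_dst[axis] = slice(None, -1)
            sl_src[axis] = slice(1, None)
        rolled[tuple(sl_dst)] = t[tuple(sl_src)]
        ok = np.isfinite(rolled) & np.isfinite(t)
        lap[ok] += rolled[ok] - t[ok]
        count += ok
    lap[count == 0] = np.nan
    lap[~np.isfinite(t)] = np.nan
    return lap


def remove_outliers(surfaces: SurfaceSet, tau_um: float = 20.0) -> SurfaceSet:
    """Flag samples where the Laplacian of any adjacent layer thickness
    exceeds ``tau_um`` (or the thickness is negative) and mark both bounding
    surfaces missing there."""
    out = surfaces.copy()
    flag = np.zeros((N_BOUNDARIES, surfaces.n_bscans, surfaces.n_ascans), dtype=bool)
    for k in range(N_BOUNDARIES - 1):
        t = out.layer_thickness_um(k)
        lap = _masked_laplacian(t)
        bad = np.zeros(t.shape, dtype=bool)
        with np.errstate(invalid="ignore"):
            bad |= np.abs(lap) > tau_um
            bad |= t < 0  # crossings are anatomically impossible
        flag[k] |= bad
        flag[k + 1] |= bad
    out.values[flag] = np.nan
    return out


def interpolate_missing(surfaces: SurfaceSet) -> SurfaceSet:
    """PCHIP infill along the A-scan direction, per B-scan per boundary.

    Outside the outermost knots the nearest knot value is held constant.
    Rows with fewer than two knots copy the nearest B-scan with enough
    knots; a boundary with no knots anywhere raises.
    """
    out = surfaces.copy()
    x = np.arange(out.n_ascans, dtype=np.float64)
    for k in range(N_BOUNDARIES):
        plane = out.values[k]
        needy: list[int] = []
        for b in range(out.n_bscans):
            row = plane[b]
            ok = np.isfinite(row)
            if ok.sum() >= 2:
                interp = PchipInterpolator(x[ok], row[ok], extrapolate=False)
                filled = interp(x)
                lo, hi = np.flatnonzero(ok)[[0, -1]]
                filled[:lo] = row[lo]
                filled[hi + 1 :] = row[hi]
                plane[b] = filled
            else:  # <2 knots: fall back to the nearest B-scan with enough knots
                needy.append(b)
        done = [b for b in range(out.n_bscans) if b not in needy]
        if needy and not done:
            raise ValueError(f"boundary {BOUNDARY_NAMES[k]} has no valid samples in any B-scan")
        for b in needy:
            nearest = min(done, key=lambda d: abs(d - b))
            plane[b] = plane[nearest]
    return out


def smooth_surfaces(surfaces: SurfaceSet) -> SurfaceSet:
    """3x3 box smoothing over the (bscan, ascan) grid with edge replication."""
    out = surfaces.copy()
    for k in range(N_BOUNDARIES):
        out.values[k] = ndimage.uniform_filter(out.values[k], size=3, mode="nearest")
    return out


def enforce_ordering(surfaces: SurfaceSet) -> SurfaceSet:
    """Sequential top-down projection: b_k <- max(b_k, b_{k-1})."""
    out = surfaces.copy()
    np.maximum.accumulate(out.values, axis=0, out=out.values)
    return out


def postprocess_maps(
    classmaps: list[np.ndarray],
    axial_scale: float,
    tau_um: float = 20.0,
    hole_cfg: HoleFillConfig | None = None,
) -> SurfaceSet:
    """Full chain from per-B-scan 9-class maps to clean ordered surfaces."""
    filled = [fill_holes(cm, hole_cfg) for cm in classmaps]
    surf = surfaces_from_maps(filled, axial_scale)
    surf = remove_outliers(surf, tau_um)
    surf = interpolate_missing(surf)
    surf = smooth_surfaces(surf)
    return enforce_ordering(surf)
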