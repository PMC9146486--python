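"""Evaluation: per-class Dice, boundary MAE, regional thickness/volume
parameters and one-way-ANOVA ICC for test-retest reliability."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import BOUNDARY_NAMES, SurfaceSet

__all__ = [
    "dice",
    "boundary_mae",
    "ThicknessParams",
    "thickness_parameters",
    "icc_oneway",
]

#: thickness parameters: (top boundary index, bottom boundary index)
_PARAM_BOUNDS = {
    "mRNFL": (0, 1),  # ILM .. RNFL-GCL
    "GCIPL": (1, 2),  # RNFL-GCL .. IPL-INL
    "INL": (2, 3),  # IPL-INL .. INL-OPL
    "GCC": (0, 2),  # ILM .. IPL-INL
    "TM": (0, 7),  # ILM .. BM
}


def dice(a: np.ndarray, b: np.ndarray, classes: list[int] | None = None) -> dict[int, float]:
    """Per-class Dice similarity coefficient between two label maps.

    DSC_k = 2|A_k ∩ B_k| / (|A_k| + |B_k|); defined as 1 when the class is
    absent from both maps.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if classes is None:
        classes = sorted(set(np.unique(a)) | set(np.unique(b)))
    out: dict[int, float] = {}
    for k in classes:
        ak = a == k
        bk = b == k
        denom = int(ak.sum()) + int(bk.sum())
        out[int(k)] = 1.0 if denom == 0 else 2.0 * int((ak & bk).sum()) / denom
    return out


def boundary_mae(pred: SurfaceSet, gold: SurfaceSet) -> dict:
    """Per-boundary (MAE, SD) of |pred - gold| in μm, plus the overall mean.

    The overall value is the mean of the per-boundary MAEs.
    """
    if pred.values.shape != gold.values.shape:
        raise ValueError("surface grids do not match")
    err = np.abs(pred.values - gold.values) * gold.axial_scale
    per = {}
    for k, name in enumerate(BOUNDARY_NAMES):
        e = err[k][np.isfinite(err[k])]
        per[name] = (float(e.mean()), float(e.std()))
    overall = float(np.mean([m for m, _ in per.values()]))
    return {"per_boundary": per, "overall_mae": overall}


@dataclass
class ThicknessParams:
    """Region-averaged thickness (μm) and volume (mm³) per standard parameter."""

    thickness_um: dict[str, float]
    volume_mm3: dict[str, float]
    region_diameter_mm: float
    n_samples: int


def thickness_parameters(
    surfaces: SurfaceSet,
    lateral_scale: float,
    bscan_spacing: float,
    fovea: tuple[int, int],
    region_diameter_mm: float = 5.0,
) -> ThicknessParams:
    """Standard parameters within a circular region centered on the fovea.

    Thickness is the mean over all grid samples inside the circle; volume is
    mean thickness times the circle area.
    """
    if not surfaces.is_complete():
        raise ValueError("surfaces must be complete (run postprocessing first)")
    fb, fa = fovea
    nb, na = surfaces.n_bscans, surfaces.n_ascans
    if not (0 <= fb < nb and 0 <= fa < na):
        raise ValueError(f"fovea {fovea} outside the surface grid {(nb, na)}")
    db = (np.arange(nb) - fb) * bscan_spacing / 1000.0  # mm
    da = (np.arange(na) - fa) * lateral_scale / 1000.0
    dist = np.sqrt(db[:, None] ** 2 + da[None, :] ** 2)
    radius = region_diameter_mm / 2.0
    mask = dist <= radius
    if not mask.any():
        raise ValueError("analysis region contains no grid samples")
    area_mm2 = np.pi * radius**2

    thickness: dict[str, float] = {}
    volume: dict[str, float] = {}
    for name, (top, bot) in _PARAM_BOUNDS.items():
        t_um = (surfaces.values[bot] - surfaces.values[top]) * surfaces.axial_scale
        mean_um = float(t_um[mask].mean())
        thickness[name] = mean_um
        volume[name] = mean_um / 1000.0 * area_mm2
    return ThicknessParams(thickness, volume, region_diameter_mm, int(mask.sum()))


def icc_oneway(data: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(1,1) with its confidence interval from one-way ANOVA components.

    ``data`` is subjects x repeats. Returns (icc, lower, upper).
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 repeats")
    n, k = x.shape
    grand = x.mean()
    ss_between = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_within = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum()
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    if msw == 0.0 and msb == 0.0:
        raise ValueError("degenerate data: no variance at all")
    if msw == 0.0:
        return 1.0, 1.0, 1.0
    icc = (msb - msw) / (msb + (k - 1) * msw)
    f_obs = msb / msw
    df1, df2 = n - 1, n * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lower = (f_l - 1) / (f_l + k - 1)
    upper = (f_u - 1) / (f_u + k - 1)
    return float(icc), float(lower), float(upper)
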