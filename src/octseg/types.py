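"""Shared domain types used across the pipeline.

Conventions: axial row 0 is the top of the image (vitreous side); surface
positions are row indices increasing downward; columns are 0-based A-scan
indices. Pixel intensities are floats in [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: Boundary names, ordered top to bottom.
BOUNDARY_NAMES: tuple[str, ...] = (
    "ILM",
    "RNFL-GCL",
    "IPL-INL",
    "INL-OPL",
    "OPL-ONL",
    "ELM",
    "EZ-OS",
    "BM",
)

#: Layer names (region between consecutive boundaries), ordered top to bottom.
LAYER_NAMES: tuple[str, ...] = ("mRNFL", "GCIPL", "INL", "OPL", "ONL", "MZ", "OL")

#: 9-class vocabulary: 1 = vitreous, 2..8 = the seven retinal layers, 9 = below BM.
CLASS_NAMES_9: tuple[str, ...] = ("vitreous",) + LAYER_NAMES + ("b-BM",)
CLASS_NAMES_3: tuple[str, ...] = ("above-ILM", "retina", "below-BM")

N_BOUNDARIES = len(BOUNDARY_NAMES)


class FormatError(ValueError):
    """Raised for malformed on-disk data or metadata."""


class QualityError(RuntimeError):
    """Raised when an input volume fails a quality precondition."""


@dataclass
class BScanImage:
    """A single 2-D grayscale OCT cross-section (rows = axial, cols = lateral)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("B-scan pixels must be 2-D")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class OCTVolume:
    """Ordered stack of B-scans plus physical scales.

    ``axial_scale`` and ``lateral_scale`` are in μm/px, ``bscan_spacing``
    in μm between consecutive B-scans. ``fovea`` is an optional
    (bscan index, ascan index) pair.
    """

    bscans: list[BScanImage]
    axial_scale: float
    lateral_scale: float
    bscan_spacing: float
    fovea: Optional[tuple[int, int]] = None
    volume_id: str = "volume"

    def __post_init__(self) -> None:
        if not self.bscans:
            raise ValueError("volume must contain at least one B-scan")
        shapes = {b.pixels.shape for b in self.bscans}
        if len(shapes) > 1:
            raise FormatError(f"B-scans have mismatched shapes: {sorted(shapes)}")
        for name in ("axial_scale", "lateral_scale", "bscan_spacing"):
            if not getattr(self, name) > 0:
                raise FormatError(f"{name} must be > 0")

    @property
    def n_bscans(self) -> int:
        return len(self.bscans)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.bscans), *self.bscans[0].pixels.shape)

    def as_array(self) -> np.ndarray:
        return np.stack([b.pixels for b in self.bscans])


@dataclass
class SurfaceSet:
    """Eight ordered boundary surfaces sampled per (B-scan, A-scan).

    ``values`` has shape (8, n_bscans, n_ascans); missing samples are NaN.
    """

    values: np.ndarray
    axial_scale: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 2:  # single B-scan convenience
            self.values = self.values[:, None, :]
        if self.values.ndim != 3 or self.values.shape[0] != N_BOUNDARIES:
            raise ValueError(
                f"surface values must have shape (8, n_bscans, n_ascans), got {self.values.shape}"
            )

    @property
    def n_bscans(self) -> int:
        return self.values.shape[1]

    @property
    def n_ascans(self) -> int:
        return self.values.shape[2]

    def copy(self) -> "SurfaceSet":
        return SurfaceSet(self.values.copy(), self.axial_scale)

    def is_complete(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def is_ordered(self, strict: bool = False) -> bool:
        d = np.diff(self.values, axis=0)
        d = d[np.isfinite(d)]
        return bool((d > 0).all() if strict else (d >= 0).all())

    def boundary(self, name: str) -> np.ndarray:
        try:
            return self.values[BOUNDARY_NAMES.index(name)]
        except ValueError:
            raise KeyError(f"unknown boundary {name!r}") from None

    def layer_thickness_um(self, layer_index: int) -> np.ndarray:
        """Thickness map (μm) of the layer between boundaries k and k+1."""
        return (self.values[layer_index + 1] - self.values[layer_index]) * self.axial_scale
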