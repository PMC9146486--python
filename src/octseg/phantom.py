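"""Synthetic macular OCT phantom generator.

Produces B-scans with exact ground-truth class maps and boundary surfaces:
smooth ordered surfaces with a Gaussian foveal pit (inner layers pinch
toward zero thickness at the pit center), per-layer reflectivity bands,
optional hypo-reflective microcysts confined to the INL, Gaussian blur and
multiplicative gamma speckle. Everything is a pure function of the
parameter set and its seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .types import (
    BOUNDARY_NAMES,
    LAYER_NAMES,
    BScanImage,
    OCTVolume,
    SurfaceSet,
)

__all__ = [
    "PhantomParams",
    "GroundTruth",
    "generate_surfaces",
    "render_bscan",
    "classmap_from_surfaces",
    "collapse_labels",
    "generate_volume",
    "generate_dataset",
]

#: default mean layer thicknesses in μm (mRNFL, GCIPL, INL, OPL, ONL, MZ, OL)
DEFAULT_THICKNESS_UM = (25.0, 70.0, 35.0, 30.0, 80.0, 25.0, 60.0)

#: default mean reflectivity per 9-class region (vitreous .. below-BM);
#: the region under BM is moderately bright, as the choroid is in real scans
DEFAULT_REFLECTIVITY = (0.05, 0.75, 0.35, 0.25, 0.55, 0.15, 0.65, 0.85, 0.30)

_N_INNER = 4  # mRNFL, GCIPL, INL, OPL pinch at the fovea


class PhantomParameterError(ValueError):
    pass


class RenderError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomParams:
    image_height: int = 512
    image_width: int = 512
    axial_scale: float = 3.87  # μm/px
    lateral_scale: float = 11.7  # μm/px
    n_bscans: int = 25
    layer_thickness_means: tuple[float, ...] = DEFAULT_THICKNESS_UM
    thickness_jitter_sd: float = 3.0  # μm
    foveal_pit_depth: float = 120.0  # μm
    foveal_pit_sigma: float = 300.0  # μm
    layer_reflectivity: tuple[float, ...] = DEFAULT_REFLECTIVITY
    speckle_shape: float = 8.0  # gamma shape; 0 disables speckle
    blur_sigma: float = 0.5  # px; 0 disables blur
    microcyst_rate: float = 0.0  # expected cysts per B-scan
    thin_rnfl: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.image_height, self.image_width, self.n_bscans) <= 0:
            raise PhantomParameterError("image dimensions and B-scan count must be positive")
        if len(self.layer_thickness_means) != len(LAYER_NAMES):
            raise PhantomParameterError(f"need {len(LAYER_NAMES)} layer thickness means")
        if any(t <= 0 for t in self.layer_thickness_means):
            raise PhantomParameterError("all layer thickness means must be > 0")
        if len(self.layer_reflectivity) != 9:
            raise PhantomParameterError("need 9 reflectivity values")
        if any(not 0.0 <= r <= 1.0 for r in self.layer_reflectivity):
            raise PhantomParameterError("reflectivity values must lie in [0, 1]")
        if min(self.axial_scale, self.lateral_scale) <= 0:
            raise PhantomParameterError("pixel scales must be > 0")
        if self.thickness_jitter_sd < 0 or self.foveal_pit_depth < 0:
            raise PhantomParameterError("jitter sd and pit depth must be >= 0")

    @property
    def bscan_spacing(self) -> float:
        """μm between B-scans (square lateral footprint)."""
        return self.image_width * self.lateral_scale / self.n_bscans

    @property
    def fovea_center(self) -> tuple[int, int]:
        return (self.n_bscans - 1) // 2, (self.image_width - 1) // 2


@dataclass
class GroundTruth:
    surfaces: SurfaceSet
    classmap9: np.ndarray
    classmap3: np.ndarray


def _smooth_field(rng: np.random.Generator, x_norm: np.ndarray, b_norm: float) -> np.ndarray:
    """Zero-mean, unit-ish-sd smooth low-frequency field along one B-scan row."""
    n_terms = 0
    out = np.zeros_like(x_norm)
    for i in range(1, 4):
        for j in range(3):
            amp = rng.normal()
            phase = rng.uniform(0, 2 * np.pi)
            out += amp * np.cos(2 * np.pi * (i * x_norm + j * b_norm) + phase)
            n_terms += 1
    return out / np.sqrt(n_terms / 2.0)


def generate_surfaces(params: PhantomParams, bscan_index: int) -> SurfaceSet:
    """Ground-truth boundary surfaces (px) for one B-scan of the phantom volume."""
    params.validate()
    h, w = params.image_height, params.image_width
    ax = params.axial_scale
    x = np.arange(w, dtype=np.float64)
    x_norm = x / w

    bc, xc = params.fovea_center
    du = (x - xc) * params.lateral_scale
    db = (bscan_index - bc) * params.bscan_spacing
    sigma = params.foveal_pit_sigma
    pit = np.exp(-(du**2 + db**2) / (2.0 * sigma**2))

    # jitter fields drawn from the volume-level seed so every call is reproducible
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    b_norm = bscan_index / max(params.n_bscans, 1)
    base_field = _smooth_field(rng, x_norm, b_norm)
    layer_fields = [_smooth_field(rng, x_norm, b_norm) for _ in LAYER_NAMES]

    means_px = np.asarray(params.layer_thickness_means) / ax
    total_px = means_px.sum()
    base_row = max(2.0, (h - total_px) * 0.38)
    jit_px = params.thickness_jitter_sd / ax

    thick = np.empty((len(LAYER_NAMES), w))
    for k in range(len(LAYER_NAMES)):
        thick[k] = means_px[k] + jit_px * layer_fields[k]
    if params.thin_rnfl:
        thick[0] *= np.linspace(0.25, 1.0, w)

    inner_sum_um = float(np.sum(params.layer_thickness_means[:_N_INNER]))
    pinch = min(1.0, params.foveal_pit_depth / inner_sum_um) if inner_sum_um > 0 else 0.0
    thick[:_N_INNER] *= 1.0 - pinch * pit[None, :]
    np.clip(thick, 0.05, None, out=thick)

    pit_px = params.foveal_pit_depth / ax
    ilm = base_row + jit_px * base_field + pit_px * pit

    values = np.empty((len(BOUNDARY_NAMES), w))
    values[0] = ilm
    for k in range(len(LAYER_NAMES)):
        values[k + 1] = values[k] + thick[k]
    return SurfaceSet(values[:, None, :], axial_scale=ax)


def classmap_from_surfaces(surfaces: SurfaceSet, image_height: int, bscan: int = 0) -> np.ndarray:
    """9-class map: region k occupies rows [surface_{k-1}, surface_k) per column."""
    return _classmap9(surfaces.values[:, bscan, :], image_height)


def _classmap9(surface_rows: np.ndarray, image_height: int) -> np.ndarray:
    rows = np.arange(image_height, dtype=np.float64)[:, None]
    cmap = np.ones((image_height, surface_rows.shape[1]), dtype=np.uint8)
    for k in range(surface_rows.shape[0]):
        cmap += (rows >= surface_rows[k][None, :]).astype(np.uint8)
    return cmap


def collapse_labels(classmap9: np.ndarray) -> np.ndarray:
    """Collapse 9-class labels to 3: 1 -> 1 (vitreous), 2..8 -> 2 (retina), 9 -> 3."""
    cm = np.asarray(classmap9)
    if cm.size and (cm.min() < 1 or cm.max() > 9):
        bad = sorted(set(np.unique(cm)) - set(range(1, 10)))
        raise ValueError(f"labels outside 1..9: {bad}")
    out = np.full(cm.shape, 2, dtype=np.uint8)
    out[cm == 1] = 1
    out[cm == 9] = 3
    return out


def render_bscan(
    surfaces: SurfaceSet, params: PhantomParams, bscan_index: int = 0
) -> tuple[BScanImage, GroundTruth]:
    """Render one B-scan from its ground-truth surfaces.

    Pipeline: per-region reflectivity -> microcysts (dark ellipses inside the
    INL, labels untouched) -> Gaussian blur -> multiplicative gamma speckle
    -> clip to [0, 1].
    """
    params.validate()
    h, w = params.image_height, params.image_width
    s = surfaces.values[:, 0, :]
    if s.shape[1] != w:
        raise RenderError(f"surfaces have {s.shape[1]} A-scans, image width is {w}")
    if not np.isfinite(s).all() or s.min() < 0 or s.max() > h:
        raise RenderError("surfaces exceed the image bounds")

    cmap9 = _classmap9(s, h)
    cmap3 = collapse_labels(cmap9)
    refl = np.asarray(params.layer_reflectivity, dtype=np.float64)
    img = refl[cmap9 - 1]

    if params.microcyst_rate > 0:
        rng_c = np.random.default_rng(np.random.SeedSequence([params.seed, bscan_index, 2]))
        inl = cmap9 == 4
        n_cysts = rng_c.poisson(params.microcyst_rate)
        rows = np.arange(h, dtype=np.float64)[:, None]
        cols = np.arange(w, dtype=np.float64)[None, :]
        for _ in range(n_cysts):
            cx = rng_c.uniform(0, w - 1)
            j = int(round(cx))
            top, bot = s[2, j], s[3, j]
            if bot - top < 2.0:
                continue
            cy = 0.5 * (top + bot)
            ry = rng_c.uniform(1.0, max(1.0, 0.5 * (bot - top)))
            rx = rng_c.uniform(0.006 * w, 0.025 * w)
            ellipse = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
            img[ellipse & inl] = 0.03

    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma)
    if params.speckle_shape > 0:
        rng_s = np.random.default_rng(np.random.SeedSequence([params.seed, bscan_index, 1]))
        img = img * rng_s.gamma(params.speckle_shape, 1.0 / params.speckle_shape, img.shape)
    img = np.clip(img, 0.0, 1.0)

    gt = GroundTruth(surfaces=surfaces, classmap9=cmap9, classmap3=cmap3)
    return BScanImage(img), gt


def generate_volume(params: PhantomParams) -> tuple[OCTVolume, list[GroundTruth]]:
    """Render all B-scans of one phantom volume."""
    params.validate()
    bscans: list[BScanImage] = []
    truths: list[GroundTruth] = []
    for b in range(params.n_bscans):
        surf = generate_surfaces(params, b)
        img, gt = render_bscan(surf, params, b)
        bscans.append(img)
        truths.append(gt)
    vol = OCTVolume(
        bscans=bscans,
        axial_scale=params.axial_scale,
        lateral_scale=params.lateral_scale,
        bscan_spacing=params.bscan_spacing,
        fovea=params.fovea_center,
        volume_id=f"phantom-seed{params.seed}",
    )
    return vol, truths


def volume_surfaces(truths: list[GroundTruth]) -> SurfaceSet:
    """Stack per-B-scan ground-truth surfaces into one volume SurfaceSet."""
    values = np.concatenate([t.surfaces.values for t in truths], axis=1)
    return SurfaceSet(values, axial_scale=truths[0].surfaces.axial_scale)


def _save_png(path: Path, array: np.ndarray) -> None:
    Image.fromarray(np.asarray(array, dtype=np.uint8), mode="L").save(path)


def generate_dataset(params: PhantomParams, n_volumes: int, out_dir: str | Path) -> dict:
    """Write a phantom dataset to disk and return its manifest.

    Layout per volume: ``bscan_###.png`` (8-bit grayscale), ``mask9_###.png``,
    ``mask3_###.png``, ``surfaces.csv``, ``meta.json``; a top-level
    ``manifest.json`` lists every file with the seed that generated it.
    """
    import pandas as pd

    params.validate()
    if n_volumes < 1:
        raise PhantomParameterError("n_volumes must be >= 1")
    root = Path(out_dir)
    if root.exists() and any(root.iterdir()):
        raise FileExistsError(f"output directory {root} is not empty")
    root.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"n_volumes": n_volumes, "base_seed": params.seed, "volumes": []}
    for v in range(n_volumes):
        vparams = replace(params, seed=params.seed + v)
        vol_id = f"vol{v:03d}"
        vdir = root / vol_id
        vdir.mkdir()
        files: list[str] = []
        rows = []
        for b in range(vparams.n_bscans):
            surf = generate_surfaces(vparams, b)
            img, gt = render_bscan(surf, vparams, b)
            _save_png(vdir / f"bscan_{b:03d}.png", np.round(img.pixels * 255.0))
            _save_png(vdir / f"mask9_{b:03d}.png", gt.classmap9)
            _save_png(vdir / f"mask3_{b:03d}.png", gt.classmap3)
            files += [f"bscan_{b:03d}.png", f"mask9_{b:03d}.png", f"mask3_{b:03d}.png"]
            s = surf.values[:, 0, :]
            for k, name in enumerate(BOUNDARY_NAMES):
                for a in range(vparams.image_width):
                    rows.append((b, a, name, s[k, a]))
        df = pd.DataFrame(rows, columns=["bscan", "ascan", "boundary_name", "row_px"])
        df.to_csv(vdir / "surfaces.csv", index=False)
        meta = {
            "volume_id": vol_id,
            "axial_scale": vparams.axial_scale,
            "lateral_scale": vparams.lateral_scale,
            "bscan_spacing": vparams.bscan_spacing,
            "seed": vparams.seed,
            "params": dataclasses.asdict(vparams),
        }
        (vdir / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        files += ["surfaces.csv", "meta.json"]
        manifest["volumes"].append({"id": vol_id, "seed": vparams.seed, "files": files})
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
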