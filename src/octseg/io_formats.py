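"""Readers and writers for volumes, surfaces and metadata.

Two on-disk volume representations are supported: a directory of per-B-scan
images (PNG or TIFF, 8- or 16-bit, with a ``meta.json``) and a single HDF5
container (``/bscans`` 3-D dataset with scale attributes). Integer pixel
data are rescaled to [0, 1] on load. Surfaces travel as long-format CSV with
missing samples encoded as empty fields.
"""
from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .types import BOUNDARY_NAMES, BScanImage, FormatError, OCTVolume, SurfaceSet

__all__ = ["read_volume", "write_volume", "read_surfaces", "write_surfaces"]

_BSCAN_RE = re.compile(r"^bscan_(\d+)\.(png|tif|tiff)$")
_META_SCALES = ("axial_scale", "lateral_scale", "bscan_spacing")


def _load_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected a 2-D grayscale image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        maxval = np.iinfo(arr.dtype).max
        return arr.astype(np.float64) / maxval
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def _read_meta(path: Path) -> dict:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing meta.json in {path}")
    meta = json.loads(meta_path.read_text())
    for key in _META_SCALES:
        if key not in meta:
            raise FormatError(f"meta.json missing required scale field {key!r}")
        if not meta[key] > 0:
            raise FormatError(f"meta.json field {key!r} must be > 0")
    return meta


def _read_volume_dir(path: Path) -> OCTVolume:
    meta = _read_meta(path)
    indexed: dict[int, Path] = {}
    for p in sorted(path.iterdir()):
        m = _BSCAN_RE.match(p.name)
        if m:
            indexed[int(m.group(1))] = p
    if not indexed:
        raise FormatError(f"no B-scan images found in {path}")
    expected = range(min(indexed), max(indexed) + 1)
    missing = [i for i in expected if i not in indexed]
    if missing:
        raise FormatError(f"missing B-scan indices {missing} in {path}")
    pixels = [_load_image(indexed[i]) for i in expected]
    shapes = {a.shape for a in pixels}
    if len(shapes) > 1:
        raise FormatError(f"ragged B-scan shapes in {path}: {sorted(shapes)}")
    fovea = tuple(meta["fovea"]) if meta.get("fovea") is not None else None
    return OCTVolume(
        bscans=[BScanImage(a) for a in pixels],
        axial_scale=float(meta["axial_scale"]),
        lateral_scale=float(meta["lateral_scale"]),
        bscan_spacing=float(meta["bscan_spacing"]),
        fovea=fovea,
        volume_id=str(meta.get("volume_id", path.name)),
    )


def _read_volume_h5(path: Path) -> OCTVolume:
    with h5py.File(path, "r") as f:
        if "bscans" not in f:
            raise FormatError(f"{path}: HDF5 volume must contain a /bscans dataset")
        data = np.asarray(f["bscans"])
        attrs = dict(f["bscans"].attrs)
    if data.ndim != 3:
        raise FormatError(f"{path}: /bscans must be 3-D (bscan, row, col)")
    for key in _META_SCALES:
        if key not in attrs:
            raise FormatError(f"{path}: missing HDF5 attribute {key!r}")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    fovea = tuple(int(v) for v in attrs["fovea"]) if "fovea" in attrs else None
    return OCTVolume(
        bscans=[BScanImage(a) for a in data],
        axial_scale=float(attrs["axial_scale"]),
        lateral_scale=float(attrs["lateral_scale"]),
        bscan_spacing=float(attrs["bscan_spacing"]),
        fovea=fovea,
        volume_id=str(attrs.get("volume_id", path.stem)),
    )


def read_volume(path: str | Path) -> OCTVolume:
    """Load a volume from a dataset directory or an HDF5 container."""
    path = Path(path)
    if path.is_dir():
        return _read_volume_dir(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_volume_h5(path)
    raise FormatError(f"{path}: not a dataset directory or .h5/.hdf5 file")


def write_volume(volume: OCTVolume, path: str | Path, fmt: str = "dir") -> None:
    """Write a volume as a directory of 16-bit PNGs + meta.json, or as HDF5."""
    path = Path(path)
    if fmt == "h5":
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("bscans", data=volume.as_array().astype(np.float64))
            ds.attrs["axial_scale"] = volume.axial_scale
            ds.attrs["lateral_scale"] = volume.lateral_scale
            ds.attrs["bscan_spacing"] = volume.bscan_spacing
            ds.attrs["volume_id"] = volume.volume_id
            if volume.fovea is not None:
                ds.attrs["fovea"] = list(volume.fovea)
        return
    if fmt != "dir":
        raise ValueError("fmt must be 'dir' or 'h5'")
    path.mkdir(parents=True, exist_ok=True)
    for i, b in enumerate(volume.bscans):
        arr = np.round(np.clip(b.pixels, 0, 1) * 65535).astype(np.uint16)
        Image.fromarray(arr).save(path / f"bscan_{i:03d}.png")
    meta = {
        "volume_id": volume.volume_id,
        "axial_scale": volume.axial_scale,
        "lateral_scale": volume.lateral_scale,
        "bscan_spacing": volume.bscan_spacing,
        "fovea": list(volume.fovea) if volume.fovea is not None else None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def write_surfaces(surfaces: SurfaceSet, path: str | Path) -> None:
    """Write surfaces as long-format CSV; missing samples become empty fields."""
    nb, na = surfaces.n_bscans, surfaces.n_ascans
    b_idx, a_idx = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    frames = []
    for k, name in enumerate(BOUNDARY_NAMES):
        frames.append(
            pd.DataFrame(
                {
                    "bscan": b_idx.ravel(),
                    "ascan": a_idx.ravel(),
                    "boundary_name": name,
                    "row_px": surfaces.values[k].ravel(),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    header = f"# axial_scale={surfaces.axial_scale!r}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.9g")


def read_surfaces(path: str | Path) -> SurfaceSet:
    """Read a surfaces CSV written by :func:`write_surfaces`."""
    path = Path(path)
    axial_scale = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# axial_scale="):
            axial_scale = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    unknown = set(df["boundary_name"].unique()) - set(BOUNDARY_NAMES)
    if unknown:
        raise FormatError(f"unknown boundary names: {sorted(unknown)}")
    nb = int(df["bscan"].max()) + 1
    na = int(df["ascan"].max()) + 1
    values = np.full((len(BOUNDARY_NAMES), nb, na), np.nan)
    for k, name in enumerate(BOUNDARY_NAMES):
        sub = df[df["boundary_name"] == name]
        values[k, sub["bscan"].to_numpy(), sub["ascan"].to_numpy()] = sub["row_px"].to_numpy()
    return SurfaceSet(values, axial_scale=axial_scale)
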