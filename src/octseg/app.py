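"""End-to-end experiment drivers: the parameter-count report and the
reproducible phantom benchmark (a scaled-down analogue of the clinical
evaluation, runnable on one CPU)."""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import losses
from .cascade import ArrayDataset, TrainSpec, make_is_input, predict_volume, train_stage
from .metrics import boundary_mae, dice
from .networks import (
    IS_PRESET,
    RS_PRESET,
    NetConfig,
    UNet,
    analytic_parameter_count,
    analytic_unet_count,
    build_compressed_unet,
    build_reference_unet,
    count_trainable_parameters,
)
from .phantom import PhantomParams, classmap_from_surfaces, generate_volume, volume_surfaces
from .postprocess import HoleFillConfig, postprocess_maps, surfaces_from_maps
from .types import SurfaceSet

__all__ = [
    "RunConfig",
    "format_param_count",
    "run_param_report",
    "BenchmarkConfig",
    "run_phantom_benchmark",
    "corrupt_classmaps",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass
class RunConfig:
    """Single-file JSON configuration; unknown keys are rejected on load."""

    data_dir: str = "data"
    checkpoint_dir: str = "checkpoints"
    output_dir: str = "outputs"
    seed: int = 0
    tau_um: float = 20.0
    region_diameter_mm: float = 5.0
    extent_mm: float = 6.0
    rs_config: dict = field(default_factory=lambda: dataclasses.asdict(RS_PRESET))
    is_config: dict = field(default_factory=lambda: dataclasses.asdict(IS_PRESET))
    train: dict = field(default_factory=lambda: dataclasses.asdict(TrainSpec()))
    hole_fill: dict = field(default_factory=lambda: dataclasses.asdict(HoleFillConfig()))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    def stage_seed(self, offset: int) -> int:
        """Fan the global seed out to per-stage seeds by fixed offsets."""
        return self.seed * 1000 + offset


# ---------------------------------------------------------------------------
# parameter report
# ---------------------------------------------------------------------------
def format_param_count(n: int) -> str:
    """Round small counts to the nearest thousand; larger counts truncate in
    millions (two decimals below 10 M displayed with leading 0.xx, one
    decimal below 10 M, whole millions above)."""
    if n < 100_000:
        return f"{round(n / 1000)}K"
    if n < 1_000_000:
        return f"{math.trunc(n / 10_000) / 100:.2f}M"
    if n < 10_000_000:
        return f"{math.trunc(n / 100_000) / 10:.1f}M"
    return f"{round(n / 1_000_000)}M"


_REPORT_VARIANTS: list[tuple[str, NetConfig]] = [
    ("RS f=5 c=4 (preset)", RS_PRESET),
    ("RS f=5 c=8", NetConfig(n=1, o=3, f=5, c=8)),
    ("IS f=5 c=16 (preset)", IS_PRESET),
    ("IS f=3 c=8", NetConfig(n=2, o=9, f=3, c=8)),
    ("IS f=3 c=32", NetConfig(n=2, o=9, f=3, c=32)),
]


def run_param_report(out_path: Optional[str | Path] = None) -> dict:
    """Build every reported architecture variant, count parameters and
    check the framework count against the closed-form oracle."""
    rows = []
    for name, cfg in _REPORT_VARIANTS:
        model = build_compressed_unet(cfg)
        n = count_trainable_parameters(model)
        analytic = analytic_parameter_count(cfg)
        rows.append(
            {
                "model": name,
                "f": cfg.f,
                "c": cfg.c,
                "n": cfg.n,
                "o": cfg.o,
                "parameters": n,
                "analytic": analytic,
                "formatted": format_param_count(n),
                "match": n == analytic,
            }
        )
    ref = build_reference_unet(1, 3)
    n_ref = count_trainable_parameters(ref)
    rows.append(
        {
            "model": "U-Net reference (n=1, o=3)",
            "f": 3,
            "c": 64,
            "n": 1,
            "o": 3,
            "parameters": n_ref,
            "analytic": analytic_unet_count(1, 3, 3, (64, 128, 256, 512, 1024)),
            "formatted": format_param_count(n_ref),
            "match": n_ref == analytic_unet_count(1, 3, 3, (64, 128, 256, 512, 1024)),
        }
    )
    n_rs = rows[0]["parameters"]
    report = {
        "rows": rows,
        "unet_rs_ratio": n_ref // n_rs,
        "unet_rs_ratio_exact": n_ref / n_rs,
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# phantom benchmark
# ---------------------------------------------------------------------------
@dataclass
class BenchmarkConfig:
    """Scaled-down end-to-end benchmark: 128 px B-scans, light networks."""

    image_size: int = 128
    axial_scale: float = 3.0  # retina fills most of the axial range
    lateral_scale: float = 46.8
    bscans_per_volume: int = 25
    n_train_volumes: int = 12  # 12 x 25 = 300 B-scans
    n_val_volumes: int = 2
    n_test_volumes: int = 2
    rs_c: int = 4
    rs_f: int = 5
    is_c: int = 8
    is_f: int = 3
    dropout_rate: float = 0.2
    rs_epochs: int = 6
    is_epochs: int = 7
    patience: int = 5
    batch_size: int = 8
    seed: int = 0
    tau_um: float = 20.0
    dsc_threshold: float = 0.85
    mae_px_threshold: float = 2.0
    recovery_mae_px_threshold: float = 1.0
    microcyst_rate: float = 0.5
    thin_rnfl_fraction: float = 0.25

    def phantom_params(self, seed: int, thin: bool = False) -> PhantomParams:
        return PhantomParams(
            image_height=self.image_size,
            image_width=self.image_size,
            axial_scale=self.axial_scale,
            lateral_scale=self.lateral_scale,
            n_bscans=self.bscans_per_volume,
            foveal_pit_sigma=self.lateral_scale * self.image_size / 5.0,
            microcyst_rate=self.microcyst_rate,
            thin_rnfl=thin,
            seed=seed,
        )


def _collect_split(cfg: BenchmarkConfig, n_volumes: int, seed0: int):
    """Generate phantom volumes and stack images / labels / ground truth."""
    vols, images, maps3, maps9, gts = [], [], [], [], []
    for v in range(n_volumes):
        thin = (v % max(1, round(1 / cfg.thin_rnfl_fraction))) == 0 if cfg.thin_rnfl_fraction else False
        params = cfg.phantom_params(seed0 + v, thin=thin)
        vol, truths = generate_volume(params)
        vols.append((vol, truths))
        for b, t in zip(vol.bscans, truths):
            images.append(b.pixels.astype(np.float32))
            maps3.append(t.classmap3)
            maps9.append(t.classmap9)
        gts.append(volume_surfaces(truths))
    return vols, np.stack(images), np.stack(maps3), np.stack(maps9), gts


def corrupt_classmaps(
    classmaps: list[np.ndarray],
    rng: np.random.Generator,
    hole_fraction: float = 0.01,
    spike_fraction: float = 0.005,
    spike_px: tuple[float, float] = (5.0, 15.0),
) -> list[np.ndarray]:
    """Inject single-pixel label holes and local boundary spikes into maps."""
    out = []
    for cm in classmaps:
        cm = cm.copy()
        h, w = cm.shape
        n_holes = int(round(hole_fraction * cm.size))
        rr = rng.integers(0, h, n_holes)
        cc = rng.integers(0, w, n_holes)
        cm[rr, cc] = rng.integers(1, 10, n_holes).astype(cm.dtype)
        n_spikes = int(round(spike_fraction * w * 8))
        for _ in range(n_spikes):
            k = int(rng.integers(1, 9))  # boundary above region k+1
            j = int(rng.integers(0, w))
            col = cm[:, j]
            rows = np.flatnonzero(col == k + 1)
            if rows.size == 0:
                continue
            top = rows[0]
            d = int(rng.uniform(*spike_px)) * (1 if rng.random() < 0.5 else -1)
            new_top = int(np.clip(top + d, 1, h - 1))
            if new_top < top:  # extend region k+1 upward
                cm[new_top:top, j] = k + 1
            else:  # push the boundary down with the label above
                cm[top:new_top, j] = cm[max(top - 1, 0), j]
        out.append(cm)
    return out


def run_phantom_benchmark(cfg: BenchmarkConfig | None = None, verbose: bool = False) -> dict:
    """Generate phantoms, train the cascade, evaluate, and test recovery.

    Returns a report dict with mean 9-class DSC, per-boundary MAE (px and
    μm), the corrupted-surface recovery MAE, and pass/fail flags.
    """
    cfg = cfg or BenchmarkConfig()
    if cfg.n_train_volumes < 1:
        raise ValueError("benchmark requires at least one training volume")
    base = cfg.seed * 1000

    _, x_tr, m3_tr, m9_tr, _ = _collect_split(cfg, cfg.n_train_volumes, base + 100)
    _, x_va, m3_va, m9_va, _ = _collect_split(cfg, cfg.n_val_volumes, base + 500)
    test_vols, x_te, m3_te, m9_te, gt_te = _collect_split(cfg, cfg.n_test_volumes, base + 700)

    size = cfg.image_size
    rs_cfg = NetConfig(h=size, w=size, n=1, o=3, f=cfg.rs_f, c=cfg.rs_c,
                       dropout_rate=cfg.dropout_rate)
    is_cfg = NetConfig(h=size, w=size, n=2, o=9, f=cfg.is_f, c=cfg.is_c,
                       dropout_rate=cfg.dropout_rate)
    rs_model = build_compressed_unet(rs_cfg, seed=base + 1)
    is_model = build_compressed_unet(is_cfg, seed=base + 2)

    rs_spec = TrainSpec(max_epochs=cfg.rs_epochs, patience=cfg.patience,
                        batch_size=cfg.batch_size, seed=base + 11)
    rs_train = ArrayDataset(x_tr[:, None], m3_tr, 3)
    rs_val = ArrayDataset(x_va[:, None], m3_va, 3)
    rs_model, rs_hist = train_stage(rs_model, rs_train, rs_val, rs_spec, verbose=verbose)

    # teacher forcing: ground-truth 3-class channel during IS training
    is_inputs_tr = np.stack([make_is_input(x, m) for x, m in zip(x_tr, m3_tr)])
    is_inputs_va = np.stack([make_is_input(x, m) for x, m in zip(x_va, m3_va)])
    is_spec = TrainSpec(max_epochs=cfg.is_epochs, patience=cfg.patience,
                        batch_size=cfg.batch_size, seed=base + 12)
    is_train = ArrayDataset(is_inputs_tr, m9_tr, 9)
    is_val = ArrayDataset(is_inputs_va, m9_va, 9)
    is_model, is_hist = train_stage(is_model, is_train, is_val, is_spec, verbose=verbose)

    # cascade inference on the test volumes
    dsc_scores: list[float] = []
    mae_px_all: list[float] = []
    mae_um_all: list[float] = []
    per_volume = []
    i = 0
    for (vol, truths), gt_surf in zip(test_vols, gt_te):
        pred_maps = predict_volume(rs_model, is_model, vol, batch_size=cfg.batch_size)
        nb = len(pred_maps)
        d = dice(np.stack(pred_maps), m9_te[i : i + nb], classes=list(range(1, 10)))
        dsc_scores.append(float(np.mean(list(d.values()))))
        try:
            pred_surf = postprocess_maps(pred_maps, vol.axial_scale, tau_um=cfg.tau_um)
            mae = boundary_mae(pred_surf, gt_surf)
            entry = {"volume": vol.volume_id, "mean_dsc": dsc_scores[-1],
                     "mae_px": mae["overall_mae"] / vol.axial_scale,
                     "per_boundary_um": mae["per_boundary"]}
            mae_um_all.append(mae["overall_mae"])
            mae_px_all.append(entry["mae_px"])
        except ValueError as exc:
            # a class absent from every prediction: surfaces are unrecoverable
            entry = {"volume": vol.volume_id, "mean_dsc": dsc_scores[-1],
                     "mae_px": float("inf"), "postprocess_error": str(exc)}
            mae_um_all.append(float("inf"))
            mae_px_all.append(float("inf"))
        per_volume.append(entry)
        i += nb

    # corrupted ground-truth recovery (postprocessing chain in isolation)
    rng = np.random.default_rng(base + 42)
    vol0, truths0 = test_vols[0]
    clean_maps = [classmap_from_surfaces(t.surfaces, cfg.image_size) for t in truths0]
    corrupted = corrupt_classmaps(clean_maps, rng)
    recovered = postprocess_maps(corrupted, vol0.axial_scale, tau_um=cfg.tau_um)
    rec_mae = boundary_mae(recovered, gt_te[0])
    rec_mae_px = rec_mae["overall_mae"] / vol0.axial_scale

    mean_dsc = float(np.mean(dsc_scores))
    mean_mae_px = float(np.mean(mae_px_all))
    report = {
        "config": dataclasses.asdict(cfg),
        "rs_history": {"stopped_epoch": rs_hist.stopped_epoch, "val_acc": rs_hist.val_acc,
                       "val_dsc": rs_hist.val_dsc},
        "is_history": {"stopped_epoch": is_hist.stopped_epoch, "val_acc": is_hist.val_acc,
                       "val_dsc": is_hist.val_dsc},
        "mean_dsc_9class": mean_dsc,
        "mean_boundary_mae_px": mean_mae_px,
        "mean_boundary_mae_um": float(np.mean(mae_um_all)),
        "per_volume": per_volume,
        "recovery_mae_px": rec_mae_px,
        "pass_dsc": mean_dsc >= cfg.dsc_threshold,
        "pass_mae": mean_mae_px <= cfg.mae_px_threshold,
        "pass_recovery": rec_mae_px <= cfg.recovery_mae_px_threshold,
    }
    report["pass"] = bool(report["pass_dsc"] and report["pass_mae"] and report["pass_recovery"])
    return report
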