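"""Two-stage training and inference.

The retina-segmentation stage (RS) sees the raw B-scan; its 3-class argmax
map, encoded to {0.0, 0.5, 1.0}, joins the image as the second channel of
the intraretinal stage (IS). IS is trained with teacher forcing (the
ground-truth 3-class channel) and evaluated with the predicted RS output.
Training minimizes the class-weighted focal loss with Adam and early
stopping on validation pixel accuracy.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from . import losses
from .networks import UNet
from .nn import Adam, softmax
from .types import BScanImage, OCTVolume

__all__ = [
    "TrainSpec",
    "TrainHistory",
    "ArrayDataset",
    "train_stage",
    "make_is_input",
    "predict_volume",
    "save_checkpoint",
    "load_checkpoint",
]

_RS_ENCODING = np.array([0.0, 0.5, 1.0], dtype=np.float32)  # above / retina / below


@dataclass
class TrainSpec:
    learning_rate: float = 0.001
    max_epochs: int = 80
    patience: int = 10
    batch_size: int = 8
    seed: int = 0
    gamma: float = 2.0
    class_weights: Optional[np.ndarray] = None  # None -> derived from the training labels

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 < self.patience:
            raise ValueError("patience must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0

    def __len__(self) -> int:
        return len(self.val_acc)


class ArrayDataset:
    """In-memory dataset of (input, integer-label) pairs.

    ``inputs``: (N, C, H, W) float32 in [0, 1]; ``labels``: (N, H, W) int
    with 1-based classes.
    """

    def __init__(self, inputs: np.ndarray, labels: np.ndarray, n_classes: int) -> None:
        self.inputs = np.ascontiguousarray(inputs, dtype=np.float32)
        self.labels = np.ascontiguousarray(labels)
        self.n_classes = n_classes
        if len(self.inputs) != len(self.labels) or self.inputs.ndim != 4:
            raise ValueError("inputs and labels must be aligned (N,C,H,W) / (N,H,W)")
        if len(self.inputs) == 0:
            raise ValueError("empty dataset")

    def __len__(self) -> int:
        return len(self.inputs)

    def onehot(self, idx: np.ndarray) -> np.ndarray:
        lab = self.labels[idx] - 1
        eye = np.eye(self.n_classes, dtype=np.float32)
        return eye[lab].transpose(0, 3, 1, 2)

    def batches(self, batch_size: int, rng: np.random.Generator) -> Iterator[np.ndarray]:
        order = rng.permutation(len(self))
        for i in range(0, len(self), batch_size):
            yield order[i : i + batch_size]


def _pixel_accuracy(model: UNet, data: ArrayDataset, batch_size: int) -> float:
    correct = 0
    for i in range(0, len(data), batch_size):
        logits = model.forward(data.inputs[i : i + batch_size])
        pred = logits.argmax(axis=1) + 1
        correct += int((pred == data.labels[i : i + batch_size]).sum())
    return correct / (data.labels.size)


def _mean_dsc(model: UNet, data: ArrayDataset, batch_size: int) -> float:
    from .metrics import dice

    scores: list[float] = []
    for i in range(0, len(data), batch_size):
        logits = model.forward(data.inputs[i : i + batch_size])
        pred = logits.argmax(axis=1) + 1
        d = dice(pred, data.labels[i : i + batch_size], classes=list(range(1, data.n_classes + 1)))
        scores.append(float(np.mean(list(d.values()))))
    return float(np.mean(scores))


def train_stage(
    model: UNet,
    train_data: ArrayDataset,
    val_data: ArrayDataset,
    spec: TrainSpec,
    max_steps: Optional[int] = None,
    verbose: bool = False,
) -> tuple[UNet, TrainHistory]:
    """Train one cascade stage with Adam + weighted focal loss.

    Stops when validation accuracy has not improved for ``spec.patience``
    epochs or at ``spec.max_epochs``; the best-validation weights are
    restored before returning.
    """
    weights = spec.class_weights
    if weights is None:
        weights = losses.class_weights(train_data.labels, train_data.n_classes)
    weights = np.asarray(weights, dtype=np.float64)

    opt = Adam(model.params(), lr=spec.learning_rate)
    rng = np.random.default_rng(spec.seed)
    history = TrainHistory()
    best_acc = -np.inf
    best_state: dict[str, np.ndarray] | None = None
    since_improved = 0
    steps_done = 0

    for epoch in range(1, spec.max_epochs + 1):
        epoch_losses: list[float] = []
        epoch_correct = 0
        for idx in train_data.batches(spec.batch_size, rng):
            x = train_data.inputs[idx]
            onehot = train_data.onehot(idx)
            logits = model.forward(x, train=True)
            probs = softmax(logits.astype(np.float64), axis=1)
            loss = losses.weighted_focal_loss(probs, onehot, weights, spec.gamma, class_axis=1)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss ({loss}) at epoch {epoch}, step {steps_done}; aborting"
                )
            epoch_losses.append(loss)
            gprob = losses.focal_loss_grad(probs, onehot, weights, spec.gamma, class_axis=1)
            # chain through softmax: dL/dz_i = p_i (g_i - sum_j p_j g_j)
            glogits = probs * (gprob - (probs * gprob).sum(axis=1, keepdims=True))
            opt.zero_grad()
            model.backward(glogits.astype(np.float32))
            opt.step()
            pred = logits.argmax(axis=1) + 1
            epoch_correct += int((pred == train_data.labels[idx]).sum())
            steps_done += 1
            if max_steps is not None and steps_done >= max_steps:
                break

        history.train_loss.append(float(np.mean(epoch_losses)))
        history.train_acc.append(epoch_correct / train_data.labels.size)
        val_acc = _pixel_accuracy(model, val_data, spec.batch_size)
        history.val_acc.append(val_acc)
        history.val_dsc.append(_mean_dsc(model, val_data, spec.batch_size))
        history.stopped_epoch = epoch
        if verbose:
            print(
                f"epoch {epoch}: loss={history.train_loss[-1]:.5f} "
                f"train_acc={history.train_acc[-1]:.4f} val_acc={val_acc:.4f} "
                f"val_dsc={history.val_dsc[-1]:.4f}"
            )

        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_improved = 0
        else:
            since_improved += 1
        if since_improved >= spec.patience:
            break
        if max_steps is not None and steps_done >= max_steps:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def make_is_input(bscan: BScanImage | np.ndarray, rs_map: np.ndarray) -> np.ndarray:
    """Stack the image with the encoded 3-class retina map -> (2, H, W)."""
    img = bscan.pixels if isinstance(bscan, BScanImage) else np.asarray(bscan)
    rs_map = np.asarray(rs_map)
    if img.shape != rs_map.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs RS map {rs_map.shape}")
    encoded = _RS_ENCODING[rs_map - 1]
    return np.stack([img.astype(np.float32), encoded])


def predict_volume(
    rs_model: UNet, is_model: UNet, volume: OCTVolume, batch_size: int = 8
) -> list[np.ndarray]:
    """Run the cascade on every B-scan; returns per-B-scan 9-class maps."""
    h, w = volume.bscans[0].pixels.shape
    x = volume.as_array().astype(np.float32)[:, None, :, :]
    maps: list[np.ndarray] = []
    for i in range(0, len(x), batch_size):
        rs_logits = rs_model.forward(x[i : i + batch_size])
        rs_map = rs_logits.argmax(axis=1) + 1
        is_in = np.stack(
            [make_is_input(x[i + j, 0], rs_map[j]) for j in range(len(rs_map))]
        )
        is_logits = is_model.forward(is_in)
        maps.extend(list((is_logits.argmax(axis=1) + 1).astype(np.uint8)))
    return maps


def save_checkpoint(model: UNet, path: str | Path) -> None:
    np.savez(path, **model.state_dict())


def load_checkpoint(model: UNet, path: str | Path) -> UNet:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
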