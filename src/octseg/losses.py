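"""Focal loss, class-weighted focal loss, and frequency-derived class weights.

Conventions: probability tensors carry an explicit class axis; ground truth
is one-hot with the same shape. Each pixel contributes the focal term of
its true class (``p_t`` = predicted probability of the true label); terms
are grouped per class, normalized by the total pixel count and summed, so
per-class weights keep their meaning regardless of image size and the sum
equals the familiar pixel-mean focal loss. The standard minus sign is
applied: the loss is non-negative and minimized.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

EPS = 1e-7

__all__ = ["LossConfig", "ClassFrequencies", "class_frequencies", "class_weights",
           "focal_loss", "weighted_focal_loss", "focal_loss_grad"]


@dataclass
class LossConfig:
    alpha: float = 0.25
    gamma: float = 2.0
    class_weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=np.float64)
            if np.any(w < 0) or np.any(w > 1):
                raise ValueError("class weights must lie in [0, 1]")
            self.class_weights = w


@dataclass
class ClassFrequencies:
    """Foreground pixel counts per class over a pooled label stack."""

    n_foreground: np.ndarray  # per class
    n_total: int

    @property
    def fractions(self) -> np.ndarray:
        return self.n_foreground / self.n_total


def class_frequencies(label_stack: np.ndarray, n_classes: int) -> ClassFrequencies:
    """Count per-class foreground pixels over a stack of integer label maps.

    Labels are 1-based (1..n_classes).
    """
    labels = np.asarray(label_stack)
    if labels.size == 0:
        raise ValueError("empty label stack")
    counts = np.bincount(labels.ravel(), minlength=n_classes + 1)[1 : n_classes + 1]
    return ClassFrequencies(counts.astype(np.float64), int(labels.size))


def class_weights(label_stack: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class weight w = 1 - n_foreground / n_total, pooled over the stack."""
    freq = class_frequencies(label_stack, n_classes)
    return 1.0 - freq.fractions


def _check_probs(pred: np.ndarray, onehot: np.ndarray, class_axis: int) -> None:
    if pred.shape != onehot.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {onehot.shape}")
    if np.any(pred < -1e-5) or np.any(pred > 1 + 1e-5):
        raise ValueError("predicted probabilities outside [0, 1]")
    sums = pred.sum(axis=class_axis)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError("predicted probabilities must sum to 1 over classes")


def _per_class_terms(pred: np.ndarray, onehot: np.ndarray, gamma: float,
                     class_axis: int) -> np.ndarray:
    """Per-class focal terms, averaged over all pixels.

    Each pixel contributes -(1-p_t)^gamma log(p_t) to its true class only
    (p_t is the predicted probability of the true class); the class term is
    that sum divided by the total pixel count, so the terms add up to the
    familiar pixel-mean focal loss.
    """
    pt = np.clip(pred, EPS, 1.0 - EPS)
    contrib = np.where(onehot > 0.5, -((1.0 - pt) ** gamma) * np.log(pt), 0.0)
    ca = class_axis % pred.ndim
    axes = tuple(a for a in range(pred.ndim) if a != ca)
    n_pixels = pred.size // pred.shape[ca]
    return contrib.sum(axis=axes) / n_pixels


def focal_loss(pred_probs: np.ndarray, onehot_gt: np.ndarray,
               cfg: LossConfig | None = None, class_axis: int = -3) -> float:
    """Scalar focal loss: alpha * sum over classes of pixel-mean terms."""
    cfg = cfg or LossConfig()
    pred = np.asarray(pred_probs, dtype=np.float64)
    gt = np.asarray(onehot_gt, dtype=np.float64)
    _check_probs(pred, gt, class_axis)
    terms = _per_class_terms(pred, gt, cfg.gamma, class_axis)
    return float(cfg.alpha * terms.sum())


def weighted_focal_loss(pred_probs: np.ndarray, onehot_gt: np.ndarray,
                        weights: Sequence[float], gamma: float = 2.0,
                        class_axis: int = -3) -> float:
    """Focal loss with the constant alpha replaced by a per-class weight."""
    pred = np.asarray(pred_probs, dtype=np.float64)
    gt = np.asarray(onehot_gt, dtype=np.float64)
    _check_probs(pred, gt, class_axis)
    w = np.asarray(weights, dtype=np.float64)
    n_classes = pred.shape[class_axis % pred.ndim]
    if w.shape != (n_classes,):
        raise ValueError(f"need one weight per class ({n_classes}), got shape {w.shape}")
    present = np.moveaxis(gt, class_axis, 0).reshape(n_classes, -1).any(axis=1)
    if np.any(present & ~np.isfinite(w)):
        raise ValueError("missing weight for a class present in the ground truth")
    terms = _per_class_terms(pred, gt, gamma, class_axis)
    return float((w * terms).sum())


def focal_loss_grad(pred_probs: np.ndarray, onehot_gt: np.ndarray,
                    weights: Sequence[float], gamma: float = 2.0,
                    class_axis: int = 1) -> np.ndarray:
    """Gradient of the weighted focal loss w.r.t. the predicted probabilities.

    Used by the training loop, which chains it through the softmax Jacobian.
    """
    pred = np.asarray(pred_probs, dtype=np.float64)
    gt = np.asarray(onehot_gt, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    ca = class_axis % pred.ndim
    wshape = [1] * pred.ndim
    wshape[ca] = -1
    wv = w.reshape(wshape)

    is_true = gt > 0.5
    pt = np.clip(pred, EPS, 1.0 - EPS)
    # d/dp of -(1-p)^g log(p), applied only where the class is the true one
    dl_dp = gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt) - (1.0 - pt) ** gamma / pt
    n_pixels = pred.size // pred.shape[ca]
    return np.where(is_true, wv * dl_dp / n_pixels, 0.0)
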