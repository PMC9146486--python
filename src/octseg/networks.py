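"""Segmentation network builders and parameter accounting.

One parametrized encoder-decoder template covers both cascade stages: the
retina-segmentation stage (RS) and the intraretinal-layer stage (IS) differ
only in kernel size ``f``, base channel depth ``c``, input channels ``n``
and output classes ``o``. A classic full-size U-Net is provided as the
reference point for the compression comparison.

Encoder: 4 stages of two same-padded f x f convolutions (ReLU), channel
depth doubling per stage, 2x2 max pooling between stages, dropout after
stages 3 and 4. Decoder: 2x2 stride-2 transposed convolution halving
channels, concatenation with the matching encoder skip, two f x f
convolutions; a final 1x1 convolution maps to ``o`` classes. No batch
normalization anywhere.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Conv2d, ConvTranspose2x2, Dropout, Layer, MaxPool2x2, Param, ReLU, softmax

__all__ = [
    "NetConfig",
    "RS_PRESET",
    "IS_PRESET",
    "UNet",
    "build_compressed_unet",
    "build_reference_unet",
    "count_trainable_parameters",
    "analytic_parameter_count",
    "analytic_unet_count",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters of the compressed encoder-decoder."""

    h: int = 512
    w: int = 512
    n: int = 1
    o: int = 3
    f: int = 5
    c: int = 4
    dropout_rate: float = 0.5
    stages: int = 4

    def __post_init__(self) -> None:
        div = 2 ** (self.stages - 1)
        if self.h % div or self.w % div:
            raise ConfigError(f"h and w must be divisible by {div} for {self.stages} stages")
        if min(self.h, self.w, self.n, self.o, self.c) < 1 or self.f < 1:
            raise ConfigError("all architecture dimensions must be positive")
        if self.f % 2 != 1:
            raise ConfigError("kernel size must be odd (same padding)")

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(self.c * 2**i for i in range(self.stages))


RS_PRESET = NetConfig(h=512, w=512, n=1, o=3, f=5, c=4)
IS_PRESET = NetConfig(h=512, w=512, n=2, o=9, f=5, c=16)


class UNet:
    """Encoder-decoder network with skip concatenation, built from nn layers."""

    def __init__(
        self,
        in_channels: int,
        out_classes: int,
        kernel: int,
        encoder_channels: tuple[int, ...],
        dropout_stages: tuple[int, ...] = (),
        dropout_rate: float = 0.5,
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.out_classes = out_classes
        self.encoder_channels = tuple(encoder_channels)
        n = len(self.encoder_channels)

        self.enc_stages: list[list[Layer]] = []
        cin = in_channels
        for i, ch in enumerate(self.encoder_channels):
            stage: list[Layer] = [
                Conv2d(cin, ch, kernel, rng, f"enc{i}a"),
                ReLU(),
                Conv2d(ch, ch, kernel, rng, f"enc{i}b"),
                ReLU(),
            ]
            if i in dropout_stages:
                stage.append(Dropout(dropout_rate, rng))
            self.enc_stages.append(stage)
            cin = ch
        self.pools = [MaxPool2x2() for _ in range(n - 1)]

        self.ups: list[ConvTranspose2x2] = []
        self.dec_stages: list[list[Layer]] = []
        for j in range(n - 1):
            cskip = self.encoder_channels[j]
            cup = self.encoder_channels[j + 1]
            self.ups.append(ConvTranspose2x2(cup, cskip, rng, f"up{j}"))
            self.dec_stages.append(
                [
                    Conv2d(2 * cskip, cskip, kernel, rng, f"dec{j}a"),
                    ReLU(),
                    Conv2d(cskip, cskip, kernel, rng, f"dec{j}b"),
                    ReLU(),
                ]
            )
        self.head = Conv2d(self.encoder_channels[0], out_classes, 1, rng, "head")
        # near-uniform initial class probabilities: every class receives
        # gradient from the start, which prevents rare-class collapse
        self.head.W.value *= 0.01
        self._gskips: list[np.ndarray] | None = None

    # -- parameters ------------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for stage in self.enc_stages:
            for layer in stage:
                out.extend(layer.params())
        for up, stage in zip(self.ups, self.dec_stages):
            out.extend(up.params())
            for layer in stage:
                out.extend(layer.params())
        out.extend(self.head.params())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"{i}:{p.name}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(state) != len(params):
            raise ValueError("state dict does not match model")
        for i, p in enumerate(params):
            key = f"{i}:{p.name}"
            if key not in state or state[key].shape != p.value.shape:
                raise ValueError(f"missing or mismatched parameter {key}")
            p.value[...] = state[key]

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Return logits of shape (N, o, H, W) for input (N, n, H, W)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected input (N, {self.in_channels}, H, W), got {x.shape}")
        n = len(self.enc_stages)
        skips: list[np.ndarray] = []
        for i, stage in enumerate(self.enc_stages):
            for layer in stage:
                x = layer.forward(x, train)
            skips.append(x)
            if i < n - 1:
                x = self.pools[i].forward(x, train)
        for j in reversed(range(n - 1)):
            x = self.ups[j].forward(x, train)
            x = np.concatenate([skips[j], x], axis=1)
            for layer in self.dec_stages[j]:
                x = layer.forward(x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        return self.head.forward(x, train)

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(logits); returns d(loss)/d(input)."""
        n = len(self.enc_stages)
        g = self.head.backward(np.ascontiguousarray(glogits, dtype=np.float32))
        gskips: list[np.ndarray | None] = [None] * (n - 1)
        for j in range(n - 1):
            for layer in reversed(self.dec_stages[j]):
                g = layer.backward(g)
            csk = self.encoder_channels[j]
            gskips[j] = g[:, :csk]
            g = self.ups[j].backward(np.ascontiguousarray(g[:, csk:]))
        for i in reversed(range(n)):
            for layer in reversed(self.enc_stages[i]):
                g = layer.backward(g)
            if i > 0:
                g = self.pools[i - 1].backward(g)
                g = g + gskips[i - 1]
        return g

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (N, o, H, W); softmax over classes."""
        return softmax(self.forward(x, train=False), axis=1)


def build_compressed_unet(cfg: NetConfig, seed: int = 0) -> UNet:
    """Build the compressed cascade-stage network from its configuration."""
    return UNet(
        in_channels=cfg.n,
        out_classes=cfg.o,
        kernel=cfg.f,
        encoder_channels=cfg.encoder_channels,
        dropout_stages=(cfg.stages - 2, cfg.stages - 1),
        dropout_rate=cfg.dropout_rate,
        seed=seed,
    )


def build_reference_unet(n: int = 1, o: int = 3, seed: int = 0) -> UNet:
    """Classic 5-level U-Net (64..1024 channels, 3x3 kernels)."""
    return UNet(
        in_channels=n,
        out_classes=o,
        kernel=3,
        encoder_channels=(64, 128, 256, 512, 1024),
        seed=seed,
    )


def count_trainable_parameters(model: UNet) -> int:
    """Sum of all trainable weight and bias elements."""
    return int(sum(p.size for p in model.params()))


def analytic_unet_count(n_in: int, o: int, f: int, channels: tuple[int, ...]) -> int:
    """Closed-form layer-by-layer parameter count for the U-Net template.

    Serves as an independent oracle for :func:`count_trainable_parameters`.
    """
    total = 0
    cin = n_in
    for ch in channels:
        total += f * f * cin * ch + ch  # first conv of the stage
        total += f * f * ch * ch + ch  # second conv
        cin = ch
    for j in reversed(range(len(channels) - 1)):
        cskip, cup = channels[j], channels[j + 1]
        total += 4 * cup * cskip + cskip  # 2x2 stride-2 transposed conv
        total += f * f * (2 * cskip) * cskip + cskip  # conv after skip concat
        total += f * f * cskip * cskip + cskip
    total += channels[0] * o + o  # 1x1 output conv
    return total


def analytic_parameter_count(cfg: NetConfig) -> int:
    return analytic_unet_count(cfg.n, cfg.o, cfg.f, cfg.encoder_channels)
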