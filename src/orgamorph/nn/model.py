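"""Multi-scale residual U-Net for brightfield organoid segmentation.

Encoder–decoder with skip connections.  Each block learns features at two
receptive-field scales at once — parallel 3x3 and 7x7 convolution branches,
concatenated and fused by a 1x1 convolution — and carries a residual
shortcut (1x1-projected when the channel count changes).  The dual-kernel
design targets the wide size range of organoids in one frame: small buds
need the tight kernel, large cysts the wide one.  Downsampling is 2x max
pooling; upsampling is 2x nearest-neighbor followed by a 1x1 channel-halving
convolution; the head is a 1x1 convolution with a sigmoid, giving one
foreground-probability map the same size as the input.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ..io import BinaryMask, OrganoidImage
from .ops import BatchNorm2d, Conv2d, MaxPool2, Param, ReLU, Sigmoid, UpsampleNearest2

__all__ = [
    "ModelConfig",
    "MultiScaleBlock",
    "MultiScaleResUNet",
    "build_model",
    "predict_mask",
    "save_model",
    "load_model",
]


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``depth`` encoder levels (each halves resolution), channel width
    doubling per level from ``base_channels``; kernel pair fixed at (3, 7).
    """

    depth: int = 4
    base_channels: int = 32
    kernels: tuple[int, int] = (3, 7)
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.base_channels % 2:
            raise ValueError("base_channels must be even (two equal branches)")


class MultiScaleBlock:
    """Parallel 3x3/7x7 branches -> concat -> BN/ReLU -> 1x1 fuse -> BN,
    plus residual shortcut, ReLU out."""

    def __init__(self, cin: int, cout: int, kernels: tuple[int, int], rng):
        k_small, k_large = kernels
        half = cout // 2
        self.conv_small = Conv2d(cin, half, k_small, rng)
        self.conv_large = Conv2d(cin, cout - half, k_large, rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.fuse = Conv2d(cout, cout, 1, rng)
        self.bn2 = BatchNorm2d(cout)
        self.proj = Conv2d(cin, cout, 1, rng) if cin != cout else None
        self.relu_out = ReLU()
        self.half = half

    def params(self):
        ps = (
            self.conv_small.params()
            + self.conv_large.params()
            + self.bn1.params()
            + self.fuse.params()
            + self.bn2.params()
        )
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cat = np.concatenate(
            [self.conv_small.forward(x, train), self.conv_large.forward(x, train)],
            axis=1,
        )
        h = self.relu1.forward(self.bn1.forward(cat, train), train)
        h = self.bn2.forward(self.fuse.forward(h, train), train)
        sc = x if self.proj is None else self.proj.forward(x, train)
        return self.relu_out.forward(h + sc, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        gh = self.bn2.backward(g)
        gh = self.fuse.backward(gh)
        gh = self.relu1.backward(gh)
        gcat = self.bn1.backward(gh)
        dx = self.conv_small.backward(gcat[:, : self.half])
        dx += self.conv_large.backward(gcat[:, self.half :])
        dx += g if self.proj is None else self.proj.backward(g)
        return dx


class MultiScaleResUNet:
    """The full encoder–decoder graph with explicit backward pass."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, base, ks = config.depth, config.base_channels, config.kernels
        widths = [base * 2**i for i in range(d + 1)]
        self.enc: list[MultiScaleBlock] = []
        cin = config.in_channels
        for i in range(d):
            self.enc.append(MultiScaleBlock(cin, widths[i], ks, rng))
            cin = widths[i]
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = MultiScaleBlock(widths[d - 1], widths[d], ks, rng)
        self.ups = [UpsampleNearest2() for _ in range(d)]
        self.up_convs = [
            Conv2d(widths[i + 1], widths[i], 1, rng) for i in reversed(range(d))
        ]
        self.dec = [
            MultiScaleBlock(2 * widths[i], widths[i], ks, rng)
            for i in reversed(range(d))
        ]
        self.head = Conv2d(widths[0], 1, 1, rng)
        self.sigmoid = Sigmoid()

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for b in self.enc:
            ps += b.params()
        ps += self.bottleneck.params()
        for c in self.up_convs:
            ps += c.params()
        for b in self.dec:
            ps += b.params()
        ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, 1, H, W) float in [0, 1]; returns probabilities, same shape."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        d = self.config.depth
        if min(x.shape[2], x.shape[3]) < 2**d:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} smaller than 2^depth = {2**d}"
            )
        if x.shape[2] % 2**d or x.shape[3] % 2**d:
            raise ValueError("spatial dims must be multiples of 2^depth")
        skips = []
        h = x
        for i in range(d):
            h = self.enc[i].forward(h, train)
            skips.append(h)
            h = self.pools[i].forward(h, train)
        h = self.bottleneck.forward(h, train)
        for j in range(d):
            h = self.ups[j].forward(h, train)
            h = self.up_convs[j].forward(h, train)
            h = np.concatenate([skips[d - 1 - j], h], axis=1)
            h = self.dec[j].forward(h, train)
        logits = self.head.forward(h, train)
        return self.sigmoid.forward(logits, train)

    def backward(self, grad: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(probabilities)."""
        d = self.config.depth
        g = self.sigmoid.backward(grad)
        g = self.head.backward(g)
        skip_grads = [None] * d
        for j in reversed(range(d)):
            g = self.dec[j].backward(g)
            ch = g.shape[1] // 2
            skip_grads[d - 1 - j] = g[:, :ch]
            g = self.up_convs[j].backward(g[:, ch:])
            g = self.ups[j].backward(g)
        g = self.bottleneck.backward(g)
        for i in reversed(range(d)):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        for b in self._bn_layers():
            arrays += [b.running_mean.copy(), b.running_var.copy()]
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrays[: len(ps)]):
            p.value[...] = a
        rest = arrays[len(ps) :]
        for i, b in enumerate(self._bn_layers()):
            b.running_mean[...] = rest[2 * i]
            b.running_var[...] = rest[2 * i + 1]

    def cast(self, dtype) -> "MultiScaleResUNet":
        """Cast all parameters/statistics (float64 enables FD grad checks)."""
        for p in self.params():
            p.value = p.value.astype(dtype)
            p.grad = p.grad.astype(dtype)
        for b in self._bn_layers():
            b.running_mean = b.running_mean.astype(dtype)
            b.running_var = b.running_var.astype(dtype)
        return self

    def _bn_layers(self):
        blocks = self.enc + [self.bottleneck] + self.dec
        for blk in blocks:
            yield blk.bn1
            yield blk.bn2


def build_model(config: ModelConfig | None = None) -> MultiScaleResUNet:
    return MultiScaleResUNet(config or ModelConfig())


def _normalize(image: OrganoidImage | np.ndarray) -> np.ndarray:
    arr = image.pixels if isinstance(image, OrganoidImage) else np.asarray(image)
    return arr.astype(np.float32) / 255.0


def predict_mask(
    model: MultiScaleResUNet,
    image: OrganoidImage | np.ndarray,
    threshold: float = 0.5,
) -> tuple[np.ndarray, BinaryMask]:
    """Whole-frame inference: reflect-pad to a multiple of 2^depth, forward
    in eval mode, crop back, and binarize with a strict ``> threshold``.

    Returns the probability map and the thresholded mask, both input-sized.
    """
    x = _normalize(image)
    h, w = x.shape
    f = 2**model.config.depth
    if min(h, w) < f:
        raise ValueError(f"image {h}x{w} smaller than 2^depth = {f}")
    ph = (-h) % f
    pw = (-w) % f
    xp = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
    prob = model.forward(xp[None, None], train=False)[0, 0]
    prob = prob[:h, :w]
    return prob, BinaryMask(prob > threshold)


def save_model(model: MultiScaleResUNet, path: str | Path) -> None:
    """Checkpoint the architecture config and all weights to one .npz."""
    cfg = dataclasses.asdict(model.config)
    cfg["kernels"] = list(cfg["kernels"])
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state())}
    np.savez(path, config=json.dumps(cfg), **arrays)


def load_model(path: str | Path) -> MultiScaleResUNet:
    with np.load(path, allow_pickle=False) as data:
        cfg = json.loads(str(data["config"]))
        cfg["kernels"] = tuple(cfg["kernels"])
        model = MultiScaleResUNet(ModelConfig(**cfg))
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    model.load_state(arrays)
    return model
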