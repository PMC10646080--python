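"""Training loop: random crops, paired augmentation, SGD on the compound loss.

Each epoch draws one random crop per training image, augments image and
mask with the same geometric transform (flips, rotation, affine
scale/translation) plus an image-only Gaussian blur, and takes SGD-with-
momentum steps on the dice + cross-entropy objective.  Validation runs
whole-image inference each epoch and tracks mean DSC; the returned weights
are those of the best-validation epoch.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import transform as sktf

from .evaluation import dice
from .io import BinaryMask, OrganoidImage
from .losses import compound_loss, cross_entropy_loss, dice_loss
from .nn.model import MultiScaleResUNet, predict_mask

__all__ = ["TrainConfig", "TrainHistory", "augment", "train"]

Pair = tuple  # (OrganoidImage | ndarray, BinaryMask | ndarray)


@dataclasses.dataclass
class TrainConfig:
    """Optimization and augmentation settings.

    Defaults follow the full-scale recipe — 512 px crops, batches of
    eight, SGD at learning rate 0.001 (momentum 0.9) — with augmentation
    magnitudes exposed since only the transform family is prescribed.
    """

    crop: int = 512
    batch: int = 8
    lr: float = 1e-3
    momentum: float = 0.9
    epochs: int = 200
    flip_p: float = 0.5
    rotation_deg: float = 180.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_frac: float = 0.1
    blur_sigma_range: tuple[float, float] = (0.0, 1.5)
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch < 1:
            raise ValueError("batch must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclasses.dataclass
class TrainHistory:
    """Per-epoch training losses and validation DSC."""

    loss_total: list[float] = dataclasses.field(default_factory=list)
    loss_ce: list[float] = dataclasses.field(default_factory=list)
    loss_dice: list[float] = dataclasses.field(default_factory=list)
    val_dsc: list[float] = dataclasses.field(default_factory=list)

    @property
    def best_epoch(self) -> int | None:
        if not self.val_dsc:
            return None
        return int(np.argmax(self.val_dsc))


def _as_float_image(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, OrganoidImage) else np.asarray(image)
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    return arr.astype(np.float32)


def _as_bool(mask) -> np.ndarray:
    return mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask) != 0


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    config: TrainConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random flip/rotation/affine draw to both image and mask.

    The identical geometric transform hits both arrays; the mask is
    resampled nearest-neighbor so it stays strictly binary, and Gaussian
    blur touches the image only.  With all magnitudes zero (and unit scale
    range) this is the identity.
    """
    cfg = config or TrainConfig()
    img = np.asarray(image, dtype=np.float32)
    msk = _as_bool(mask)
    if img.shape != msk.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {msk.shape}")

    if cfg.flip_p > 0 and rng.random() < cfg.flip_p:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if cfg.flip_p > 0 and rng.random() < cfg.flip_p:
        img, msk = img[::-1], msk[::-1]

    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg) if cfg.rotation_deg else 0.0
    scale = rng.uniform(*cfg.scale_range)
    h, w = img.shape
    ty = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * h if cfg.translate_frac else 0.0
    tx = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * w if cfg.translate_frac else 0.0
    if angle != 0.0 or scale != 1.0 or tx != 0.0 or ty != 0.0:
        center = np.array([w, h]) / 2.0 - 0.5
        tf = (
            sktf.AffineTransform(translation=-center)
            + sktf.AffineTransform(rotation=np.deg2rad(angle), scale=scale)
            + sktf.AffineTransform(translation=center + [tx, ty])
        )
        img = sktf.warp(img, tf.inverse, order=1, mode="reflect", preserve_range=True)
        msk = (
            sktf.warp(
                msk.astype(np.float32), tf.inverse, order=0, mode="reflect",
                preserve_range=True,
            )
            > 0.5
        )

    lo, hi = cfg.blur_sigma_range
    if hi > 0:
        sigma = rng.uniform(lo, hi)
        if sigma > 0.05:
            img = ndi.gaussian_filter(img, sigma)
    return img.astype(np.float32), msk


def _random_crop(
    img: np.ndarray, msk: np.ndarray, crop: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    h, w = img.shape
    if crop > h or crop > w:
        raise ValueError(f"crop {crop} larger than image {h}x{w}")
    r = int(rng.integers(0, h - crop + 1))
    c = int(rng.integers(0, w - crop + 1))
    return img[r : r + crop, c : c + crop], msk[r : r + crop, c : c + crop]


def _sgd_step(model: MultiScaleResUNet, velocities: list[np.ndarray], cfg: TrainConfig) -> None:
    for p, v in zip(model.params(), velocities):
        v *= cfg.momentum
        v -= cfg.lr * p.grad
        p.value += v


def train(
    model: MultiScaleResUNet,
    train_set: Sequence[Pair],
    val_set: Sequence[Pair],
    config: TrainConfig | None = None,
) -> tuple[MultiScaleResUNet, TrainHistory]:
    """Fit the network; returns it loaded with the best-validation weights.

    ``train_set`` / ``val_set`` are sequences of (image, mask) pairs; images
    may be 8-bit frames or float arrays in [0, 1].  Fully deterministic for
    a fixed config seed on one device.
    """
    cfg = config or TrainConfig()
    if not len(train_set) or not len(val_set):
        raise ValueError("train and validation sets must be non-empty")
    f = 2**model.config.depth
    if cfg.crop % f:
        raise ValueError(f"crop must be a multiple of 2^depth = {f}")
    rng = np.random.default_rng(cfg.seed)
    train_pairs = [(_as_float_image(i), _as_bool(m)) for i, m in train_set]
    history = TrainHistory()
    if cfg.epochs == 0:
        return model, history

    velocities = [np.zeros_like(p.value) for p in model.params()]
    best_state: list[np.ndarray] | None = None
    best_dsc = -1.0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(train_pairs))
        crops = []
        for idx in order:
            img, msk = train_pairs[idx]
            ci, cm = _random_crop(img, msk, cfg.crop, rng)
            ci, cm = augment(ci, cm, rng, cfg)
            crops.append((ci, cm))
        ep_tot: list[float] = []
        ep_ce: list[float] = []
        ep_dice: list[float] = []
        for start in range(0, len(crops), cfg.batch):
            chunk = crops[start : start + cfg.batch]
            x = np.stack([c[0] for c in chunk])[:, None]
            g = np.stack([c[1] for c in chunk])[:, None].astype(np.float32)
            model.zero_grad()
            prob = model.forward(x, train=True)
            total, grad = compound_loss(prob, g, return_grad=True)
            ep_tot.append(total)
            ep_ce.append(cross_entropy_loss(prob, g))
            ep_dice.append(dice_loss(prob, g))
            model.backward(grad.astype(np.float32))
            _sgd_step(model, velocities, cfg)
        history.loss_total.append(float(np.mean(ep_tot)))
        history.loss_ce.append(float(np.mean(ep_ce)))
        history.loss_dice.append(float(np.mean(ep_dice)))

        dscs = []
        for img, msk in val_set:
            _, pred = predict_mask(model, _scale_to_uint8(img), cfg.threshold)
            dscs.append(dice(pred, _as_bool(msk)))
        val = float(np.mean(dscs))
        history.val_dsc.append(val)
        if val > best_dsc:
            best_dsc = val
            best_state = model.state()

    if best_state is not None:
        model.load_state(best_state)
    return model, history


def _scale_to_uint8(image) -> np.ndarray:
    arr = image.pixels if isinstance(image, OrganoidImage) else np.asarray(image)
    if arr.dtype == np.uint8:
        return arr
    return np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
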