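"""Seeded generator of brightfield-like organoid scenes with exact ground truth.

Cystic colon organoids in Matrigel image as bright ellipsoidal lumens with a
darker rim on a grainy gray background.  The generator reproduces that regime
well enough to exercise every pipeline stage offline: in-focus organoids of
heterogeneous (lognormal) size, out-of-focus distractor blobs that ground
truth excludes, optionally border-cropped objects, multi-day growth series,
and per-well pseudo-viability values proportional to total organoid area —
mimicking a luminescence viability readout that scales with live-cell number.

Everything is driven by a single integer seed: the same (config, seed) pair
reproduces scenes bit-identically.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .io import BinaryMask, OrganoidImage

__all__ = [
    "SimConfig",
    "SimObject",
    "GrowthSeries",
    "WellPlate",
    "rasterize_ellipse",
    "generate_scene",
    "generate_growth_series",
    "generate_well_plate",
]


@dataclasses.dataclass
class SimConfig:
    """Scene parameters.

    Sizes are physical (µm) and converted through ``um_per_px``; the defaults
    describe a 96-well brightfield field of view holding a handful of cystic
    organoids between the 40 µm annotation floor and a few hundred µm.

    Parameters
    ----------
    height, width
        Frame size in pixels.
    n_organoids
        Number of in-focus organoids (ground-truth positives).
    diameter_median_um, diameter_sigma
        Median and log-scale sigma of the lognormal equivalent-diameter
        distribution, truncated to [diameter_min_um, diameter_max_um].
    ecc_range
        Eccentricity range of the elliptical outlines, subset of [0, 1).
    um_per_px
        Calibration carried onto the generated image.
    n_outfocus_distractors
        Blurred low-contrast blobs excluded from the ground-truth mask.
    allow_border_crop
        If True, organoids may be centred near the frame edge and cropped.
    noise_sigma, rim_darkness, lumen_brightness, background_level
        Intensity-model knobs (8-bit units).
    seed
        RNG seed; same config + seed gives bit-identical output.
    """

    height: int = 512
    width: int = 512
    n_organoids: int = 8
    diameter_median_um: float = 80.0
    diameter_sigma: float = 0.4
    diameter_min_um: float = 30.0
    diameter_max_um: float = 250.0
    ecc_range: tuple[float, float] = (0.0, 0.8)
    um_per_px: float = 2.0
    n_outfocus_distractors: int = 0
    allow_border_crop: bool = False
    noise_sigma: float = 8.0
    rim_darkness: float = 45.0
    lumen_brightness: float = 60.0
    background_level: float = 115.0
    rim_width_px: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("frame must be at least 1x1")
        if not (0 < self.diameter_min_um <= self.diameter_max_um):
            raise ValueError("diameter bounds must be positive and ordered")
        lo, hi = self.ecc_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("ecc_range must be a subset of [0, 1)")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        if self.n_organoids < 0 or self.n_outfocus_distractors < 0:
            raise ValueError("object counts must be >= 0")


@dataclasses.dataclass
class SimObject:
    """Ground truth for one rendered entity (organoid or distractor)."""

    center: tuple[float, float]  # (row, col), px
    a: float  # semi-major axis, px
    b: float  # semi-minor axis, px
    orientation: float  # radians, CCW from the column axis
    is_distractor: bool = False
    touches_border: bool = False

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")

    @property
    def area(self) -> float:
        """Analytic area pi*a*b in px^2 (before any border cropping)."""
        return float(np.pi * self.a * self.b)

    @property
    def eccentricity(self) -> float:
        return float(np.sqrt(1.0 - (self.b / self.a) ** 2))


@dataclasses.dataclass
class GrowthSeries:
    """Daily scenes for replicate wells plus paired pseudo-viability values.

    ``viability[w, d]`` is k * (total true organoid area of well w on day
    d+1) * (1 + eps), eps ~ N(0, noise^2), emulating a luminescence readout.
    """

    days: list[int]
    wells: list[str]
    scenes: dict[tuple[str, int], tuple[OrganoidImage, BinaryMask, list[SimObject]]]
    viability: np.ndarray  # (n_wells, n_days)
    total_true_area: np.ndarray  # (n_wells, n_days), px^2


@dataclasses.dataclass
class WellPlate:
    """Independent wells with paired pseudo-viability, one scene each."""

    wells: list[str]
    scenes: dict[str, tuple[OrganoidImage, BinaryMask, list[SimObject]]]
    viability: np.ndarray
    total_true_area: np.ndarray


def rasterize_ellipse(
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    orientation: float,
    shape: tuple[int, int],
) -> BinaryMask:
    """Pixel-centre rasterization of a rotated ellipse.

    A pixel (r, c) is foreground iff its centre satisfies the rotated-ellipse
    inequality ``(u/a)^2 + (v/b)^2 <= 1`` where (u, v) are the pixel-centre
    coordinates in the ellipse frame.  Fully deterministic; parts of the
    ellipse outside the frame are simply clipped.
    """
    a, b = semi_axes
    if not (a > 0 and b > 0):
        raise ValueError("semi-axes must be positive")
    h, w = shape
    cy, cx = center
    rows = np.arange(h)[:, None] - cy
    cols = np.arange(w)[None, :] - cx
    cos, sin = np.cos(orientation), np.sin(orientation)
    u = cols * cos + rows * sin
    v = -cols * sin + rows * cos
    return BinaryMask((u / a) ** 2 + (v / b) ** 2 <= 1.0)


def _sample_object(
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    distractor: bool,
    margin_scale: float = 1.0,
) -> SimObject | None:
    """Draw one object's geometry from the configured distributions.

    ``margin_scale`` reserves frame room for later linear growth: the
    border margin is computed from ``a * margin_scale`` so a growth series
    can scale objects in place without pushing them off-frame.
    """
    d_um = float(np.exp(rng.normal(np.log(cfg.diameter_median_um), cfg.diameter_sigma)))
    d_um = float(np.clip(d_um, cfg.diameter_min_um, cfg.diameter_max_um))
    r_px = 0.5 * d_um / cfg.um_per_px  # equivalent-circle radius
    ecc = rng.uniform(*cfg.ecc_range)
    # Keep pi*a*b equal to the equivalent-circle area: a = r/s, b = r*s.
    s = (1.0 - ecc**2) ** 0.25
    a, b = r_px / s, r_px * s
    theta = rng.uniform(0, np.pi)
    margin = 0.0 if (cfg.allow_border_crop and not distractor) else a * margin_scale + 2.0
    lo_r, hi_r = margin, cfg.height - margin
    lo_c, hi_c = margin, cfg.width - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        return None  # this draw does not fit the frame; caller resamples
    cy = rng.uniform(lo_r, hi_r)
    cx = rng.uniform(lo_c, hi_c)
    return SimObject((cy, cx), a, b, theta, is_distractor=distractor)


def _overlaps(obj: SimObject, others: Sequence[SimObject], pad: float = 3.0) -> bool:
    # Conservative circle test on semi-major axes keeps layouts non-touching.
    for o in others:
        d = np.hypot(obj.center[0] - o.center[0], obj.center[1] - o.center[1])
        if d < obj.a + o.a + pad:
            return True
    return False


def _touches_border(obj: SimObject, shape: tuple[int, int]) -> bool:
    mask = rasterize_ellipse(obj.center, (obj.a, obj.b), obj.orientation, shape)
    m = mask.pixels
    return bool(m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any())


def _place_objects(
    cfg: SimConfig, rng: np.random.Generator, margin_scale: float = 1.0
) -> list[SimObject]:
    objects: list[SimObject] = []
    for kind, n in (("organoid", cfg.n_organoids), ("distractor", cfg.n_outfocus_distractors)):
        for _ in range(n):
            for _attempt in range(200):
                obj = _sample_object(
                    cfg,
                    rng,
                    distractor=(kind == "distractor"),
                    margin_scale=margin_scale,
                )
                if obj is not None and not _overlaps(obj, objects):
                    break
            else:
                raise ValueError(
                    "could not place all objects without overlap; "
                    "reduce n_organoids or object sizes relative to the frame"
                )
            obj.touches_border = _touches_border(obj, (cfg.height, cfg.width))
            objects.append(obj)
    return objects


def _render(cfg: SimConfig, objects: Sequence[SimObject], rng: np.random.Generator) -> np.ndarray:
    """Paint objects onto a noisy, mildly shaded background (float image)."""
    h, w = cfg.height, cfg.width
    yy = np.linspace(-1, 1, h)[:, None]
    xx = np.linspace(-1, 1, w)[None, :]
    tilt = rng.uniform(-6, 6, size=2)
    img = cfg.background_level + tilt[0] * yy + tilt[1] * xx
    img = np.broadcast_to(img, (h, w)).copy()

    for obj in objects:
        inner = rasterize_ellipse(
            obj.center, (obj.a, obj.b), obj.orientation, (h, w)
        ).pixels
        rim_a = obj.a + cfg.rim_width_px
        rim_b = obj.b + cfg.rim_width_px
        outer = rasterize_ellipse(
            obj.center, (rim_a, rim_b), obj.orientation, (h, w)
        ).pixels
        if obj.is_distractor:
            # Out-of-focus blob: faint contrast, heavily smeared below.
            blob = np.where(inner, cfg.lumen_brightness * 0.35, 0.0)
            blob = ndi.gaussian_filter(blob, sigma=max(obj.b / 2.0, 3.0))
            img += blob
        else:
            img = np.where(outer & ~inner, img - cfg.rim_darkness, img)
            img = np.where(inner, cfg.background_level + cfg.lumen_brightness, img)

    img = ndi.gaussian_filter(img, sigma=0.6)  # mild optical softening
    img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_scene(
    config: SimConfig,
) -> tuple[OrganoidImage, BinaryMask, list[SimObject]]:
    """Generate one scene: image, exact ground-truth mask, and object truth.

    The mask is the union of the in-focus organoid rasterizations —
    distractors are excluded, border-cropped organoids are included
    (selection filters are a downstream concern, as in manual annotation).
    """
    rng = np.random.default_rng(config.seed)
    objects = _place_objects(config, rng)
    gt = np.zeros((config.height, config.width), dtype=bool)
    for obj in objects:
        if not obj.is_distractor:
            gt |= rasterize_ellipse(
                obj.center, (obj.a, obj.b), obj.orientation, gt.shape
            ).pixels
    pixels = _render(config, objects, rng)
    image = OrganoidImage(pixels, um_per_px=config.um_per_px)
    return image, BinaryMask(gt), objects


def _scaled_scene(
    cfg: SimConfig,
    base_objects: Sequence[SimObject],
    linear_scale: float,
    rng: np.random.Generator,
) -> tuple[OrganoidImage, BinaryMask, list[SimObject], float]:
    """Re-render a layout with all semi-axes scaled; clamp centres in-frame."""
    objects = []
    total_area = 0.0
    for obj in base_objects:
        a, b = obj.a * linear_scale, obj.b * linear_scale
        if 2 * a > min(cfg.height, cfg.width) - 4:
            raise ValueError("grown organoid no longer fits the frame")
        cy = float(np.clip(obj.center[0], a + 2, cfg.height - a - 2))
        cx = float(np.clip(obj.center[1], a + 2, cfg.width - a - 2))
        new = SimObject((cy, cx), a, b, obj.orientation, obj.is_distractor)
        new.touches_border = _touches_border(new, (cfg.height, cfg.width))
        objects.append(new)
        if not new.is_distractor:
            total_area += new.area
    gt = np.zeros((cfg.height, cfg.width), dtype=bool)
    for obj in objects:
        if not obj.is_distractor:
            gt |= rasterize_ellipse(
                obj.center, (obj.a, obj.b), obj.orientation, gt.shape
            ).pixels
    pixels = _render(cfg, objects, rng)
    return OrganoidImage(pixels, um_per_px=cfg.um_per_px), BinaryMask(gt), objects, total_area


def generate_growth_series(
    config: SimConfig,
    days: int = 5,
    daily_growth: float = 2.0,
    noise: float = 0.05,
    *,
    n_wells: int = 3,
    plateau_day: int | None = None,
    plateau_growth: float = 1.05,
    viability_scale: float = 1.0,
) -> GrowthSeries:
    """Simulate ``n_wells`` replicate wells imaged daily for ``days`` days.

    Organoid areas grow by ``daily_growth`` per day (semi-axes by its square
    root) until ``plateau_day``, after which the per-day area factor drops to
    ``plateau_growth`` — emulating a culture whose growth slows when it is
    due for subculture.  Viability for each (well, day) is proportional to
    the well's total true organoid area with multiplicative Gaussian noise.
    """
    if days < 2:
        raise ValueError("need at least 2 days")
    if daily_growth <= 0:
        raise ValueError("daily_growth must be > 0")
    rng = np.random.default_rng(config.seed)
    day_list = list(range(1, days + 1))
    wells = [f"W{w + 1}" for w in range(n_wells)]
    scenes: dict[tuple[str, int], tuple] = {}
    areas = np.zeros((n_wells, days))
    # reserve frame room for the final-day size so grown organoids stay
    # in-frame (they may touch each other by then, as real cultures do)
    final_area_factor = 1.0
    for day in day_list[1:]:
        final_area_factor *= (
            plateau_growth
            if (plateau_day is not None and day > plateau_day)
            else daily_growth
        )
    margin_scale = float(np.sqrt(final_area_factor))
    for w, well in enumerate(wells):
        base_cfg = dataclasses.replace(config, seed=int(rng.integers(2**31)))
        layout_rng = np.random.default_rng(base_cfg.seed)
        base_objects = _place_objects(base_cfg, layout_rng, margin_scale=margin_scale)
        cum = 1.0
        for d_idx, day in enumerate(day_list):
            if d_idx > 0:
                step = (
                    plateau_growth
                    if (plateau_day is not None and day > plateau_day)
                    else daily_growth
                )
                cum *= step
            img, gt, objs, area = _scaled_scene(
                base_cfg, base_objects, np.sqrt(cum), layout_rng
            )
            img.well, img.day = well, day
            scenes[(well, day)] = (img, gt, objs)
            areas[w, d_idx] = area
    eps = rng.normal(0.0, noise, size=areas.shape) if noise > 0 else np.zeros_like(areas)
    viability = viability_scale * areas * (1.0 + eps)
    return GrowthSeries(day_list, wells, scenes, viability, areas)


def generate_well_plate(
    config: SimConfig,
    n_wells: int = 90,
    noise: float = 0.05,
    *,
    organoid_counts: Sequence[int] | None = None,
    viability_scale: float = 1.0,
) -> WellPlate:
    """Independent wells with viability proportional to total organoid area.

    ``organoid_counts`` fixes the per-well organoid number (cycled); the
    default sweeps a two-fold serial dilution (16, 8, 4, 2, 1), the seeding
    design used to linearise a viability assay against cell number.
    """
    if organoid_counts is None:
        organoid_counts = [16, 8, 4, 2, 1]
    rng = np.random.default_rng(config.seed)
    wells = [f"W{w + 1}" for w in range(n_wells)]
    scenes: dict[str, tuple] = {}
    areas = np.zeros(n_wells)
    for w, well in enumerate(wells):
        n = int(organoid_counts[w % len(organoid_counts)])
        cfg = dataclasses.replace(
            config, n_organoids=n, seed=int(rng.integers(2**31))
        )
        img, gt, objs = generate_scene(cfg)
        img.well = well
        scenes[well] = (img, gt, objs)
        areas[w] = sum(o.area for o in objs if not o.is_distractor)
    eps = rng.normal(0.0, noise, size=areas.shape) if noise > 0 else np.zeros_like(areas)
    viability = viability_scale * areas * (1.0 + eps)
    return WellPlate(wells, scenes, viability, areas)
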