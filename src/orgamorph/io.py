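"""Image, mask and measurement-table I/O with unit calibration.

Images are 8-bit brightfield frames (JPG/PNG/TIFF); RGB input is collapsed
to a single luminance channel on read.  Binary masks use the 0/255 PNG
dialect (0 = background, 255 = organoid).  Measurement tables are CSV with
a fixed column order so downstream tooling can rely on the schema.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

__all__ = [
    "OrganoidImage",
    "BinaryMask",
    "MEASUREMENT_COLUMNS",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_measurements",
    "read_measurements",
    "render_overlay",
]

#: Fixed header of the per-organoid measurement CSV.
MEASUREMENT_COLUMNS = [
    "image_id",
    "object_id",
    "area_px",
    "area_um2",
    "equiv_diameter_px",
    "equiv_diameter_um",
    "perimeter_px",
    "perimeter_um",
    "major_axis_px",
    "major_axis_um",
    "minor_axis_px",
    "minor_axis_um",
    "eccentricity",
    "circularity",
    "roundness",
    "solidity",
]

# ITU-R BT.601 luma weights, the convention PIL's "L" mode uses.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclasses.dataclass
class OrganoidImage:
    """A single-channel 8-bit brightfield frame plus acquisition metadata.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array of intensities.
    um_per_px
        Physical calibration (micrometres per pixel), ``None`` if unknown.
        The microscope burns a scale bar into the frame; here the ratio is
        carried explicitly instead of being re-read from the bar.
    sample, day, well
        Optional acquisition metadata (organoid line, culture day, well id).
    """

    pixels: np.ndarray
    um_per_px: float | None = None
    sample: str | None = None
    day: int | None = None
    well: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("image must be a non-empty 2-D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.um_per_px is not None and not self.um_per_px > 0:
            raise ValueError(f"um_per_px must be > 0, got {self.um_per_px}")
        if self.day is not None and self.day < 0:
            raise ValueError("day must be >= 0")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclasses.dataclass
class BinaryMask:
    """Foreground/background grid; foreground pixels belong to organoids."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if len(vals) > 2:
                raise ValueError("not a binary mask: more than two distinct values")
            arr = arr != 0
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def foreground_count(self) -> int:
        return int(self.pixels.sum())


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to luminance; pass grayscale through."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        gray = arr[..., :3].astype(np.float64) @ _LUMA
        return np.clip(np.round(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported image shape {arr.shape}")


def read_image(
    path: str | Path,
    um_per_px: float | None = None,
    *,
    sample: str | None = None,
    day: int | None = None,
    well: str | None = None,
) -> OrganoidImage:
    """Read a JPG/PNG/TIFF frame, collapsing RGB to luminance.

    Raises ``ValueError`` for a non-positive calibration and propagates
    decode errors (``FileNotFoundError``, ``PIL.UnidentifiedImageError``)
    for unreadable files.
    """
    if um_per_px is not None and not um_per_px > 0:
        raise ValueError(f"um_per_px must be > 0, got {um_per_px}")
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.size == 0:
        raise ValueError(f"empty image: {path}")
    return OrganoidImage(
        _to_gray(arr), um_per_px=um_per_px, sample=sample, day=day, well=well
    )


def write_image(image: OrganoidImage | np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale frame (format chosen by file extension)."""
    arr = image.pixels if isinstance(image, OrganoidImage) else np.asarray(image)
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a 0/255 PNG mask; any file with >2 distinct values is rejected."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    vals = np.unique(arr)
    if len(vals) > 2:
        raise ValueError(
            f"not a binary mask: {path} holds {len(vals)} distinct values"
        )
    return BinaryMask(arr != 0)


def write_mask(mask: BinaryMask | np.ndarray, path: str | Path) -> None:
    arr = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask) != 0
    Image.fromarray(np.where(arr, 255, 0).astype(np.uint8), mode="L").save(path)


def write_measurements(
    records: Sequence[Mapping[str, object]], path: str | Path
) -> None:
    """Write per-organoid measurement rows to CSV in the fixed column order.

    Every record must carry the same keys (one shared schema); rows keep
    their input order.  An empty record list yields a header-only file.
    """
    records = list(records)
    if records:
        schema = set(records[0].keys())
        for r in records[1:]:
            if set(r.keys()) != schema:
                raise ValueError("heterogeneous record schemas")
        cols = [c for c in MEASUREMENT_COLUMNS if c in schema]
        cols += [c for c in records[0] if c not in cols]
        df = pd.DataFrame.from_records(records, columns=cols)
    else:
        df = pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def render_overlay(
    image: OrganoidImage | np.ndarray | None,
    contours: "LabeledContours",  # noqa: F821 - forward ref to postprocess
    path: str | Path | None = None,
    *,
    on_source: bool = False,
) -> np.ndarray:
    """Draw white object outlines with each organoid's ID at its centroid.

    By default outlines go on a black background (the contour-image
    convention); ``on_source=True`` overlays them on the input frame.
    Returns the rendered 8-bit array and optionally writes it to ``path``.
    """
    labels = contours.label_image
    if image is not None:
        arr = image.pixels if isinstance(image, OrganoidImage) else np.asarray(image)
        if arr.shape != labels.shape:
            raise ValueError(
                f"shape mismatch: image {arr.shape} vs contours {labels.shape}"
            )
    canvas = (
        np.asarray(arr, dtype=np.uint8).copy()
        if (on_source and image is not None)
        else np.zeros(labels.shape, dtype=np.uint8)
    )
    pil = Image.fromarray(canvas, mode="L")
    draw = ImageDraw.Draw(pil)
    for obj_id, boundary in contours.boundaries.items():
        # boundary is (row, col); PIL wants (x, y) = (col, row)
        xy = [(float(c), float(r)) for r, c in boundary]
        if len(xy) >= 2:
            draw.line(xy + [xy[0]], fill=255, width=1)
        rows, cols = np.nonzero(labels == obj_id)
        cy, cx = rows.mean(), cols.mean()
        draw.text((cx, cy), str(obj_id), fill=255, anchor="mm")
    out = np.asarray(pil)
    if path is not None:
        pil.save(path)
    return out
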