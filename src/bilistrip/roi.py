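"""Circular region-of-interest extraction and per-channel grayscale statistics.

The analysis window is a square of side 130 px (16,900 total points, matching
a 130 x 130 crop of the strip photograph) and the sampled region is the
inscribed disc of the 30 mm test paper.  A pixel belongs to the disc iff its
centre lies within the disc radius of the given centre (boundary ties
included); pixel centres sit at integer (row, col) coordinates, 0-based.
Grayscale means are arithmetic means of the raw stored 8-bit channel values
(no gamma linearisation), the convention of phone RGB-analysis tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import EmptyROIError, GeometryError

__all__ = [
    "ROIMask",
    "ChannelStats",
    "circular_roi_mask",
    "channel_stats",
    "load_image",
    "save_mask_png",
    "DEFAULT_WINDOW_SIDE_PX",
    "DEFAULT_DISC_DIAMETER_PX",
]

#: 130^2 = 16,900 total points in the analysis window.
DEFAULT_WINDOW_SIDE_PX = 130
DEFAULT_DISC_DIAMETER_PX = 130


@dataclass(frozen=True)
class ROIMask:
    """Boolean inclusion flags over a square window placed on an image."""

    origin: tuple[int, int]       # (row, col) of the window's top-left, 0-based
    side: int                     # window side in px
    flags: np.ndarray             # bool, side x side

    def __post_init__(self):
        flags = np.asarray(self.flags, dtype=bool)
        if flags.shape != (self.side, self.side):
            raise ValueError("flags must be a side x side boolean array")
        object.__setattr__(self, "flags", flags)
        object.__setattr__(self, "origin", (int(self.origin[0]), int(self.origin[1])))

    @property
    def count(self) -> int:
        return int(self.flags.sum())

    def with_origin(self, row: int, col: int) -> "ROIMask":
        return ROIMask((row, col), self.side, self.flags)


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and population SD of the sampled pixels."""

    mean: np.ndarray       # (R, G, B) means, counts
    sd: np.ndarray         # (R, G, B) population standard deviations
    n_pixels: int

    def __post_init__(self):
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be positive")
        if np.any(self.mean < 0) or np.any(self.mean > 255):
            raise ValueError("channel means must lie in [0, 255]")


def circular_roi_mask(window_side_px: int = DEFAULT_WINDOW_SIDE_PX,
                      diameter_px: float | None = None,
                      center: tuple[float, float] | None = None,
                      origin: tuple[int, int] = (0, 0)) -> ROIMask:
    """Disc-shaped inclusion mask inside a square window.

    ``center`` defaults to the window centre ((side-1)/2, (side-1)/2) and
    ``diameter_px`` to the window side.  A pixel is included iff its centre
    lies within diameter/2 of the centre (Euclidean, ties included).
    """
    side = int(window_side_px)
    if side < 1:
        raise GeometryError("window side must be >= 1")
    d = float(side if diameter_px is None else diameter_px)
    if d <= 0:
        raise GeometryError("diameter must be positive")
    if d > side:
        raise GeometryError(f"disc diameter {d} px exceeds window side {side} px")
    if center is None:
        center = ((side - 1) / 2.0, (side - 1) / 2.0)
    r0, c0 = float(center[0]), float(center[1])
    if not (-0.5 <= r0 <= side - 0.5 and -0.5 <= c0 <= side - 0.5):
        raise GeometryError(f"centre {center} lies outside the window")
    rr, cc = np.mgrid[0:side, 0:side]
    flags = (rr - r0) ** 2 + (cc - c0) ** 2 <= (d / 2.0) ** 2
    return ROIMask(origin=origin, side=side, flags=flags)


def _pixels(img) -> np.ndarray:
    px = img.pixels if hasattr(img, "pixels") else np.asarray(img)
    if px.ndim != 3 or px.shape[2] < 3:
        raise ValueError("image must be HxWx3 (RGB)")
    return px[:, :, :3]


def channel_stats(img, mask: ROIMask) -> ChannelStats:
    """Mean and population SD of each channel over the masked pixels."""
    px = _pixels(img)
    r0, c0 = mask.origin
    if r0 < 0 or c0 < 0 or r0 + mask.side > px.shape[0] or c0 + mask.side > px.shape[1]:
        raise GeometryError("mask window does not lie within the image")
    if mask.count == 0:
        raise EmptyROIError("mask selects no pixels")
    window = px[r0:r0 + mask.side, c0:c0 + mask.side].astype(float)
    sampled = window[mask.flags]           # (count, 3)
    return ChannelStats(mean=sampled.mean(axis=0),
                        sd=sampled.std(axis=0),     # population SD (ddof=0)
                        n_pixels=mask.count)


def load_image(path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG or TIFF); alpha is dropped."""
    px = iio.imread(Path(path))
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got {px.dtype}")
    return px[:, :, :3]


def save_mask_png(path, mask: ROIMask) -> None:
    """Export the inclusion flags as a 0/255 grayscale PNG for inspection."""
    iio.imwrite(Path(path), (mask.flags.astype(np.uint8) * 255))
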