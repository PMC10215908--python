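"""Grayscale conversion, histogramming, Otsu thresholding and white-area accounting.

All images are numpy arrays: RGB images are ``(H, W, 3)`` uint8, grayscale
images ``(H, W)`` uint8. The Otsu threshold is computed from first principles
by exhaustively maximizing the interclass variance

    g(K) = omega0(K) * omega1(K) * (mu0(K) - mu1(K))**2

where class 0 is ``{gray <= K}`` and class 1 is ``{gray > K}``.  Binarization
sends a pixel to white (255) only when its value strictly exceeds the
threshold; boundary pixels go to black.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ImageFormatError

#: ITU-R BT.601 luma weights (R, G, B). Centralized so callers can swap them.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

__all__ = [
    "BT601_WEIGHTS",
    "OtsuResult",
    "BinaryMask",
    "AreaRatio",
    "rgb_to_gray",
    "gray_histogram",
    "otsu_threshold",
    "binarize",
    "white_ratio",
    "load_image",
    "save_mask",
]


@dataclass(frozen=True)
class OtsuResult:
    """Threshold K plus the class statistics that justify it.

    ``omega0``/``mu0`` describe the low class ``{gray <= K}``,
    ``omega1``/``mu1`` the high class ``{gray > K}``. ``g`` is the interclass
    variance at K (gray-level^2 units). ``degenerate`` is set when the image
    has a single distinct gray level, in which case ``g == 0`` and K equals
    that level.
    """

    threshold: int
    omega0: float
    omega1: float
    mu0: float
    mu1: float
    g: float
    degenerate: bool = False


@dataclass(frozen=True)
class BinaryMask:
    """A {0, 255}-valued uint8 image together with the threshold that made it."""

    pixels: np.ndarray
    threshold_used: int

    def __post_init__(self):
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 255)).all():
            raise ValueError("mask contains values other than 0 and 255")


@dataclass(frozen=True)
class AreaRatio:
    """Exact white-pixel count over total pixels of a binary mask."""

    white_pixels: int
    total_pixels: int

    @property
    def ratio(self) -> float:
        return self.white_pixels / self.total_pixels


def _validate_image(img: np.ndarray, channels: int | None) -> np.ndarray:
    img = np.asarray(img)
    if channels is None:
        if img.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    else:
        if img.ndim != 3 or img.shape[2] != channels:
            raise ValueError(f"expected an (H, W, {channels}) image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("pixel values outside [0, 255]")
    return img


def rgb_to_gray(img: np.ndarray, weights: tuple[float, float, float] = BT601_WEIGHTS) -> np.ndarray:
    """Convert an (H, W, 3) RGB image to (H, W) grayscale.

    Each output pixel is ``round(wr*R + wg*G + wb*B)`` with round-half-up,
    clamped to [0, 255].
    """
    img = _validate_image(img, channels=3)
    luma = img.astype(np.float64) @ np.asarray(weights, dtype=np.float64)
    # round half up, not banker's rounding
    gray = np.floor(luma + 0.5)
    return np.clip(gray, 0, 255).astype(np.uint8)


def gray_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin histogram of a grayscale image; counts sum to H*W."""
    img = _validate_image(img, channels=None)
    return np.bincount(img.reshape(-1).astype(np.int64), minlength=256)


def otsu_threshold(hist: np.ndarray) -> OtsuResult:
    """Exhaustive-scan Otsu threshold from a 256-bin histogram.

    Scans every K in [0, 255], splitting into {gray <= K} and {gray > K};
    returns the smallest K attaining the maximal interclass variance. A
    histogram with a single occupied bin yields the degenerate result
    ``g == 0`` with K at that bin.
    """
    hist = np.asarray(hist, dtype=np.int64)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if (hist < 0).any():
        raise ValueError("histogram counts must be non-negative")
    total = int(hist.sum())
    if total == 0:
        raise ValueError("histogram is empty")

    occupied = np.flatnonzero(hist)
    if occupied.size == 1:
        level = int(occupied[0])
        return OtsuResult(threshold=level, omega0=1.0, omega1=0.0,
                          mu0=float(level), mu1=math.nan, g=0.0, degenerate=True)

    levels = np.arange(256, dtype=np.float64)
    counts = hist.astype(np.float64)
    cum_n = np.cumsum(counts)                 # pixels with gray <= K
    cum_s = np.cumsum(counts * levels)        # intensity mass with gray <= K
    n0, n1 = cum_n, total - cum_n
    w0, w1 = n0 / total, n1 / total
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(n0 > 0, cum_s / n0, 0.0)
        mu1 = np.where(n1 > 0, (cum_s[-1] - cum_s) / n1, 0.0)
    g = np.where((n0 > 0) & (n1 > 0), w0 * w1 * (mu0 - mu1) ** 2, 0.0)

    k = int(np.argmax(g))  # argmax returns the first (smallest) maximizer
    return OtsuResult(
        threshold=k,
        omega0=float(w0[k]),
        omega1=float(w1[k]),
        mu0=float(mu0[k]) if n0[k] > 0 else math.nan,
        mu1=float(mu1[k]) if n1[k] > 0 else math.nan,
        g=float(g[k]),
        degenerate=bool(g[k] == 0.0),
    )


def binarize(img: np.ndarray, threshold: int) -> BinaryMask:
    """Threshold a grayscale image: pixel > K -> 255, pixel <= K -> 0."""
    if not (0 <= threshold <= 255):
        raise ValueError(f"threshold {threshold} outside [0, 255]")
    img = _validate_image(img, channels=None)
    out = np.where(img > threshold, 255, 0).astype(np.uint8)
    return BinaryMask(pixels=out, threshold_used=int(threshold))


def white_ratio(mask: BinaryMask) -> AreaRatio:
    """Exact count of white (255) pixels and the white/total ratio."""
    white = int((mask.pixels == 255).sum())
    return AreaRatio(white_pixels=white, total_pixels=int(mask.pixels.size))


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF raster as an (H, W, 3) uint8 RGB array.

    Images carrying an alpha channel are rejected: the pipeline has no
    transparency semantics. Plain grayscale inputs are promoted to RGB.
    """
    with Image.open(path) as im:
        if im.mode in ("RGBA", "LA", "PA") or "transparency" in im.info:
            raise ImageFormatError(
                f"{path}: image has an alpha channel; flatten it before measuring")
        rgb = im.convert("RGB")
        return np.asarray(rgb, dtype=np.uint8)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a BinaryMask as an 8-bit single-channel PNG."""
    Image.fromarray(mask.pixels, mode="L").save(path, format="PNG")
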