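"""Image loading, green-channel extraction, quantization and pixel-to-µm scaling.

Fluorescence images of FITC-tagged antibody aggregates carry the analyte
signal almost exclusively in the green channel (FITC emits at ~519 nm), so
the pipeline works on the green plane of the RGB acquisition.  All internal
processing uses a row-major, origin-top-left, 0-based pixel convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MagnificationScale",
    "MAGNIFICATION_REGISTRY",
    "load_image",
    "extract_green",
    "to_uint8",
    "scale_for",
]


@dataclass(frozen=True)
class MagnificationScale:
    """Physical size of one (square) pixel at a given objective magnification."""

    name: str
    um_per_pixel: float

    def __post_init__(self) -> None:
        if not self.um_per_pixel > 0:
            raise ValueError(f"um_per_pixel must be positive, got {self.um_per_pixel}")

    @property
    def um2_per_pixel(self) -> float:
        """Area of one pixel in µm² (pixels are square: length == breadth)."""
        return self.um_per_pixel**2


#: Calibrated scale/pixel ratios for the supported objectives (µm per pixel side).
MAGNIFICATION_REGISTRY: dict[str, float] = {
    "4x": 2.667,
    "10x": 1.0416,
}


def scale_for(name: str, um_per_pixel: float | None = None) -> MagnificationScale:
    """Resolve a magnification label to a :class:`MagnificationScale`.

    Unknown labels are accepted only with an explicit ``um_per_pixel``.
    """
    if um_per_pixel is not None:
        return MagnificationScale(name, float(um_per_pixel))
    key = name.lower()
    if key not in MAGNIFICATION_REGISTRY:
        raise KeyError(
            f"unknown magnification {name!r}; known: {sorted(MAGNIFICATION_REGISTRY)} "
            "(pass um_per_pixel explicitly for a custom objective)"
        )
    return MagnificationScale(key, MAGNIFICATION_REGISTRY[key])


class ImageFormatError(ValueError):
    """Raised when a file cannot be decoded as a supported raster image."""


def load_image(path: str | Path) -> np.ndarray:
    """Load a TIFF/PNG/JPEG image as a ``(J, K, 3)`` uint8 RGB array.

    Grayscale files are replicated across the three channels (with a logged
    warning); an alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoder failure → format error
        raise ImageFormatError(f"cannot decode {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        logger.warning("%s is single-channel; replicating across RGB", path.name)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[-1] != 3:
        raise ImageFormatError(f"unsupported image shape {arr.shape} in {path}")
    if arr.dtype != np.uint8:
        # 16-bit (or other) acquisitions are linearly rescaled onto 0-255.
        arr = np.stack([to_uint8(arr[..., c].astype(np.float64)) for c in range(3)], axis=-1)
    return arr


def extract_green(img: np.ndarray) -> np.ndarray:
    """Return the green channel g(x, y) of an RGB image as uint8."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected (J, K, 3) RGB image, got shape {img.shape}")
    return np.ascontiguousarray(img[..., 1], dtype=np.uint8)


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Linearly rescale a finite-valued image onto the 0–255 working scale.

    ``[min, max]`` maps to ``[0, 255]``; rounding is half-away-from-zero so the
    quantization is bit-stable across platforms.  A constant image maps to all
    zeros (degenerate range).
    """
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("to_uint8 requires finite pixel values")
    lo = img.min()
    rng = img.max() - lo
    if rng == 0:
        return np.zeros(img.shape, dtype=np.uint8)
    scaled = (img - lo) * (255.0 / rng)
    return np.floor(scaled + 0.5).astype(np.uint8)
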