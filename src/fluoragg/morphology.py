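"""Post-threshold binary cleanup: clean, fill, close, and pixel-count filtering.

The fixed pipeline order is clean → fill → close → size filter.  ``clean``
and the size filter only ever remove foreground pixels; ``fill`` and
``close`` only ever add them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MorphologySettings",
    "clean",
    "fill",
    "close",
    "size_filter",
    "postprocess",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MorphologySettings:
    apply_clean: bool = True
    apply_fill: bool = True
    apply_close: bool = False
    min_pixels: int = 20
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.min_pixels < 0:
            raise ValueError("min_pixels must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    return mask.astype(bool)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def clean(mask: np.ndarray) -> np.ndarray:
    """Set every isolated foreground pixel (all 8 neighbors zero) to zero."""
    m = _as_bool(mask)
    neighbor_count = ndimage.convolve(
        m.astype(np.uint8), _SQUARE3.astype(np.uint8), mode="constant", cval=0
    ) - m.astype(np.uint8)
    return m & (neighbor_count > 0)


def fill(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes: background regions not 4-connected to the border."""
    return ndimage.binary_fill_holes(_as_bool(mask))


def close(mask: np.ndarray) -> np.ndarray:
    """Morphological closing (dilation then erosion) with a 3×3 square."""
    m = _as_bool(mask)
    # Pad so dilation at the border behaves as on an infinite zero canvas;
    # guarantees closing is extensive (never removes foreground).
    padded = np.pad(m, 1, mode="constant")
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=_SQUARE3), structure=_SQUARE3
    )
    return closed[1:-1, 1:-1] | m


def size_filter(mask: np.ndarray, min_pixels: int = 20, connectivity: int = 8) -> np.ndarray:
    """Remove connected components with fewer than ``min_pixels`` pixels.

    Components with exactly ``min_pixels`` pixels are kept.
    """
    if min_pixels < 0:
        raise ValueError("min_pixels must be >= 0")
    m = _as_bool(mask)
    if min_pixels == 0:
        return m
    labels, n = ndimage.label(m, structure=_structure(connectivity))
    if n == 0:
        return m
    counts = np.bincount(labels.ravel())
    keep = counts >= min_pixels
    keep[0] = False
    return keep[labels]


def postprocess(mask: np.ndarray, settings: MorphologySettings | None = None) -> np.ndarray:
    """Apply the configured cleanup chain in the fixed order."""
    settings = settings or MorphologySettings()
    m = _as_bool(mask)
    if settings.apply_clean:
        m = clean(m)
    if settings.apply_fill:
        m = fill(m)
    if settings.apply_close:
        m = close(m)
    m = size_filter(m, settings.min_pixels, settings.connectivity)
    return m
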