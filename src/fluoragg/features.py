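"""Particle labeling and morphometrics: area, perimeter, circularity, radius.

Physical quantities follow the pixel calibration of the magnification:
area = N̂ · l · b with l = b = µm/pixel, circularity = 4πA/P², and the
equivalent circle diameter φ̄ = sqrt(4A/π) (radius φ̄/2).  The perimeter P
uses the weighted boundary-step estimator of ``skimage.measure.perimeter``
(distinct weights for straight and diagonal boundary steps), scaled to µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .imgio import MagnificationScale

__all__ = [
    "ParticleRecord",
    "SizeDistribution",
    "label_particles",
    "particle_area",
    "perimeter_um",
    "circularity",
    "equivalent_diameter",
    "equivalent_radius",
    "measure_particles",
    "records_to_frame",
    "size_distribution",
    "compare_distributions",
]


@dataclass
class ParticleRecord:
    label: int
    n_pixels: int
    area_um2: float
    perimeter_um: float
    circularity: float
    eq_diameter_um: float
    eq_radius_um: float
    centroid_row: float
    centroid_col: float


@dataclass
class SizeDistribution:
    """Equivalent-radius histogram in fixed-width bins from 0 µm.

    ``bin_edges`` has one more entry than ``counts``; bins are left-closed /
    right-open, and the last bin is an overflow bin collecting every radius
    at or above its lower edge.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    total: int
    metadata: dict = field(default_factory=dict)


def label_particles(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Label connected components; returns (label image, count)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(np.asarray(mask).astype(bool), structure=structure)
    return labels, int(n)


def particle_area(n_pixels: int, scale: MagnificationScale) -> float:
    """Physical area in µm²: pixel count × pixel length × pixel breadth."""
    if n_pixels < 1:
        raise ValueError("a particle has at least one pixel")
    return n_pixels * scale.um2_per_pixel


def perimeter_um(component: np.ndarray, scale: MagnificationScale) -> float:
    """Boundary length in µm by the weighted boundary-step estimator."""
    comp = np.asarray(component).astype(bool)
    if not comp.any():
        raise ValueError("component is empty")
    p = float(measure.perimeter(comp, neighborhood=4))
    if p == 0.0:
        # Single pixel (or degenerate line): fall back to the pixel outline.
        p = 4.0 * math.sqrt(comp.sum())
    return p * scale.um_per_pixel


def circularity(area_um2: float, perimeter: float) -> float:
    """Shape compactness 4πA/P² — 1 for a circle, π/4 for a square."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * area_um2 / perimeter**2


def equivalent_diameter(area_um2: float) -> float:
    """Diameter φ̄ = sqrt(4A/π) of the circle with the particle's area."""
    if area_um2 < 0:
        raise ValueError("area must be non-negative")
    return math.sqrt(4.0 * area_um2 / math.pi)


def equivalent_radius(area_um2: float) -> float:
    """Equivalent circle radius φ̄/2 = sqrt(A/π)."""
    return equivalent_diameter(area_um2) / 2.0


def measure_particles(
    mask: np.ndarray, scale: MagnificationScale, connectivity: int = 8
) -> list[ParticleRecord]:
    """Label the mask and compute the per-particle feature table."""
    labels, n = label_particles(mask, connectivity)
    records: list[ParticleRecord] = []
    if n == 0:
        return records
    for prop in measure.regionprops(labels):
        n_pixels = int(prop.area)
        area = particle_area(n_pixels, scale)
        # regionprops' perimeter is the same weighted boundary-step estimator,
        # evaluated on the component's own bounding box.
        perim_px = float(prop.perimeter)
        if perim_px == 0.0:
            perim_px = 4.0 * math.sqrt(n_pixels)
        perim = perim_px * scale.um_per_pixel
        records.append(
            ParticleRecord(
                label=int(prop.label),
                n_pixels=n_pixels,
                area_um2=area,
                perimeter_um=perim,
                circularity=circularity(area, perim),
                eq_diameter_um=equivalent_diameter(area),
                eq_radius_um=equivalent_radius(area),
                centroid_row=float(prop.centroid[0]),
                centroid_col=float(prop.centroid[1]),
            )
        )
    return records


def records_to_frame(records: list[ParticleRecord]) -> pd.DataFrame:
    """Per-particle table with one row per labeled aggregate."""
    columns = [
        "label",
        "n_pixels",
        "area_um2",
        "perimeter_um",
        "circularity",
        "eq_diameter_um",
        "eq_radius_um",
        "centroid_row",
        "centroid_col",
    ]
    return pd.DataFrame([vars(r) for r in records], columns=columns)


def size_distribution(
    records: list[ParticleRecord],
    bin_width_um: float = 10.0,
    overflow_edge_um: float = 100.0,
) -> SizeDistribution:
    """Histogram of equivalent radii in ``bin_width_um`` bins from 0 µm.

    Radii are sorted ascending before binning; the final bin collects every
    radius at or above ``overflow_edge_um``.
    """
    if bin_width_um <= 0:
        raise ValueError("bin_width_um must be positive")
    edges = np.arange(0.0, overflow_edge_um + bin_width_um / 2, bin_width_um)
    radii = np.sort([r.eq_radius_um for r in records])
    counts = np.zeros(edges.size, dtype=int)
    if radii.size:
        idx = np.minimum(np.floor(radii / bin_width_um).astype(int), edges.size - 1)
        counts = np.bincount(idx, minlength=edges.size)
    return SizeDistribution(
        bin_edges=np.append(edges, np.inf),
        counts=counts,
        total=int(counts.sum()),
        metadata={"bin_width_um": bin_width_um, "overflow_edge_um": overflow_edge_um},
    )


def compare_distributions(dist_a: SizeDistribution, dist_b: SizeDistribution) -> pd.DataFrame:
    """Side-by-side bin counts with deltas (b − a); edges must match."""
    if dist_a.bin_edges.shape != dist_b.bin_edges.shape or not np.allclose(
        dist_a.bin_edges[:-1], dist_b.bin_edges[:-1]
    ):
        raise ValueError("distributions have different bin edges")
    lower = dist_a.bin_edges[:-1]
    upper = dist_a.bin_edges[1:]
    return pd.DataFrame(
        {
            "bin_lower_um": lower,
            "bin_upper_um": upper,
            "count_a": dist_a.counts,
            "count_b": dist_b.counts,
            "delta": dist_b.counts.astype(int) - dist_a.counts.astype(int),
        }
    )
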