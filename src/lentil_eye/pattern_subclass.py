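"""Refinement of texture groups into the five testa-pattern classes.

A morphological region analysis separates pattern foreground from the
uniform seed surface: Canny edges with adaptive thresholds, connectivity
analysis, a closing with a rectangular structuring element, contour
following, and area computation of the filled regions.  The rules are
then: rare with no significant region -> absent, rare with any ->
spotted; sparse covering more than half the seed -> complex, else
dotted; dense -> marbled unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_closing, binary_erosion, binary_fill_holes
from skimage import measure
from skimage.morphology import disk

from lentil_eye.circle_detect import SeedPatch, edge_map
from lentil_eye.synthetic_scene import TEXTURE_GROUP, PatternClass


@dataclass
class RegionStats:
    regions: list[tuple[float, tuple[int, int, int, int], np.ndarray]]
    n_significant: int
    coverage_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage_fraction <= 1.0):
            raise ValueError("coverage_fraction out of [0, 1]")
        if self.n_significant > len(self.regions):
            raise ValueError("n_significant exceeds region count")


@dataclass
class SubclassParams:
    significant_area_fraction: float = 0.005  # of the masked seed area
    spotted_min_regions: int = 1
    complex_coverage_threshold: float = 0.5
    closing_kernel: tuple[int, int] = (5, 7)  # (rows, cols) at reference scale
    reference_patch_side: int = 100  # kernel scales with patch side / this
    canny_sigma: float = 1.0
    canny_gain: float = 0.2  # lower than scene segmentation: subtler edges

    def validate(self) -> None:
        if not (0 < self.significant_area_fraction < 1):
            raise ValueError("significant_area_fraction must be in (0, 1)")
        if not (0 < self.complex_coverage_threshold < 1):
            raise ValueError("complex_coverage_threshold must be in (0, 1)")
        if self.spotted_min_regions < 1:
            raise ValueError("spotted_min_regions must be >= 1")
        if min(self.closing_kernel) < 1:
            raise ValueError("closing kernel dims must be >= 1")


def _scaled_kernel(params: SubclassParams, side: int) -> np.ndarray:
    scale = max(side / params.reference_patch_side, 1.0)
    rows = max(int(round(params.closing_kernel[0] * scale)), 1)
    cols = max(int(round(params.closing_kernel[1] * scale)), 1)
    return np.ones((rows, cols), dtype=bool)


def region_analysis(patch: SeedPatch, params: SubclassParams | None = None) -> RegionStats:
    """Find pattern regions inside the seed mask and measure their area.

    Pipeline: adaptive Canny edges -> closing (rectangular element) ->
    hole filling -> connected components -> contour following -> area.
    Coverage is total significant-region area over the masked seed area.
    """
    params = params or SubclassParams()
    params.validate()
    side = max(patch.pixels.shape[:2])
    # keep analysis off the disc rim where the seed/background edge lives
    interior = binary_erosion(patch.mask, structure=disk(max(3, side // 20)))
    seed_area = float(patch.mask.sum())

    edges = edge_map(patch.pixels, sigma=params.canny_sigma,
                     gain=params.canny_gain).raster & interior
    closed = binary_closing(edges, structure=_scaled_kernel(params, side))
    filled = binary_fill_holes(closed) & interior
    labeled = measure.label(filled, connectivity=2)

    min_area = params.significant_area_fraction * seed_area
    regions = []
    significant_area = 0.0
    n_significant = 0
    for rp in measure.regionprops(labeled):
        contours = measure.find_contours(
            np.pad(rp.image.astype(float), 1), 0.5
        )
        contour = max(contours, key=len) if contours else np.empty((0, 2))
        regions.append((float(rp.area), rp.bbox, contour))
        if rp.area >= min_area:
            n_significant += 1
            significant_area += rp.area
    coverage = min(significant_area / seed_area, 1.0) if seed_area else 0.0
    return RegionStats(regions=regions, n_significant=n_significant,
                       coverage_fraction=coverage)


def subclass_rare(stats: RegionStats, params: SubclassParams | None = None) -> PatternClass:
    """Rare texture: no significant region -> absent, otherwise spotted."""
    params = params or SubclassParams()
    if stats.n_significant >= params.spotted_min_regions:
        return PatternClass("spotted")
    return PatternClass("absent")


def subclass_sparse(stats: RegionStats, params: SubclassParams | None = None) -> PatternClass:
    """Sparse texture: regions covering more than half the seed -> complex."""
    params = params or SubclassParams()
    if stats.coverage_fraction > params.complex_coverage_threshold:
        return PatternClass("complex")
    return PatternClass("dotted")


def final_label(
    texture: str, stats: RegionStats, params: SubclassParams | None = None
) -> PatternClass:
    """Map (texture group, region stats) to the final pattern class."""
    if texture == "dense":
        return PatternClass("marbled")
    if texture == "rare":
        return subclass_rare(stats, params)
    if texture == "sparse":
        return subclass_sparse(stats, params)
    raise ValueError(f"unknown texture group: {texture!r}")


def classify_patch(
    patch: SeedPatch, texture: str, params: SubclassParams | None = None
) -> tuple[PatternClass, RegionStats]:
    """Region analysis + final rule in one call."""
    stats = region_analysis(patch, params)
    return final_label(texture, stats, params), stats
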