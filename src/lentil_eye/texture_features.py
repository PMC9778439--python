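"""198-dimensional per-seed descriptors: LBP texture + RGB color histogram.

The texture part is the rotation-invariant uniform local binary pattern
with P = 16 circular neighbors (P + 2 = 18 histogram bins); the color
part is a 60-bin histogram per RGB channel (180 bins).  Both are
accumulated over the circular seed mask only and L1-normalized per block.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import local_binary_pattern
from scipy.ndimage import binary_erosion
from skimage.morphology import disk

from lentil_eye.circle_detect import SeedPatch, to_gray

__all__ = [
    "SeedPatch",
    "FeatureVector",
    "lbp_descriptor",
    "color_histogram",
    "feature_vector",
    "LBP_POINTS",
    "LBP_RADIUS",
]

LBP_POINTS = 16
LBP_RADIUS = 2
N_LBP_BINS = LBP_POINTS + 2  # uniform patterns 0..P plus the non-uniform bin
N_COLOR_BINS = 60
N_FEATURES = N_LBP_BINS + 3 * N_COLOR_BINS  # 198

MIN_MASKED_PIXELS = 100


class InsufficientRegionError(ValueError):
    """Masked region too small for a stable texture descriptor."""


class FeatureVector:
    """LBP (18) || R (60) || G (60) || B (60) descriptor of a seed patch."""

    __slots__ = ("lbp", "color_hist")

    def __init__(self, lbp: np.ndarray, color_hist: np.ndarray):
        lbp = np.asarray(lbp, dtype=np.float64)
        color_hist = np.asarray(color_hist, dtype=np.float64)
        if lbp.shape != (N_LBP_BINS,):
            raise ValueError(f"lbp must have {N_LBP_BINS} entries")
        if color_hist.shape != (3 * N_COLOR_BINS,):
            raise ValueError(f"color_hist must have {3 * N_COLOR_BINS} entries")
        self.lbp = lbp
        self.color_hist = color_hist

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.lbp, self.color_hist])

    def __len__(self) -> int:
        return N_FEATURES

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureVector) and np.array_equal(
            self.combined, other.combined
        )


def lbp_descriptor(
    patch: SeedPatch, points: int = LBP_POINTS, radius: int = LBP_RADIUS
) -> np.ndarray:
    """Rotation-invariant uniform LBP histogram over the masked interior.

    Pixels whose circular neighborhood crosses the mask boundary are
    skipped (the mask is eroded by the LBP radius before accumulation).
    """
    if patch.mask.sum() < MIN_MASKED_PIXELS:
        raise InsufficientRegionError("masked region smaller than 100 pixels")
    # integer gray levels: float inputs make LBP comparisons noise-sensitive
    gray = np.round(to_gray(patch.pixels)).astype(np.uint8)
    codes = local_binary_pattern(gray, points, radius, method="uniform")
    # radius+1: bilinear sampling at the ring reaches one pixel beyond it
    valid = binary_erosion(patch.mask, structure=disk(radius + 1))
    if not valid.any():
        raise InsufficientRegionError("mask vanished after boundary erosion")
    n_bins = points + 2
    hist, _ = np.histogram(codes[valid], bins=np.arange(n_bins + 1) - 0.5)
    return hist / hist.sum()


def color_histogram(patch: SeedPatch, bins_per_channel: int = N_COLOR_BINS) -> np.ndarray:
    """Per-channel intensity histograms over the mask, R || G || B.

    Each 60-bin block spans [0, 255] with equal-width bins and is
    L1-normalized independently.
    """
    if not patch.mask.any():
        raise ValueError("empty mask")
    pix = np.asarray(patch.pixels)
    if pix.ndim != 3 or pix.shape[2] != 3:
        raise ValueError("patch must be RGB")
    edges = np.linspace(0.0, 255.0, bins_per_channel + 1)
    edges[-1] = 255.0 + 1e-9  # include 255 in the last bin
    blocks = []
    for ch in range(3):
        vals = pix[..., ch][patch.mask].astype(np.float64)
        hist, _ = np.histogram(vals, bins=edges)
        blocks.append(hist / hist.sum())
    return np.concatenate(blocks)


def feature_vector(patch: SeedPatch) -> FeatureVector:
    """Full 198-item descriptor: LBP followed by the color histogram."""
    return FeatureVector(lbp=lbp_descriptor(patch), color_hist=color_histogram(patch))
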