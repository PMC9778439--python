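"""Seed segmentation by randomized circle detection.

Circles are found by repeatedly sampling three edge pixels, forming their
circumcircle, and accepting candidates whose circumference is well
supported by the edge map.  Accepted circles are refined by a
least-squares fit on their inlier edge pixels, then screened by a
per-image radius statistic and by a radiometric check on the fraction of
dark background pixels inside each circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage import feature as skfeature
from skimage.filters import threshold_otsu

#: ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])

RETAINED = "retained"
DISCARDED_RADIUS = "discarded_radius"
DISCARDED_RADIOMETRIC = "discarded_radiometric"


class DegenerateGeometryError(ValueError):
    """Three sampled points are (near-)collinear; no circumcircle exists."""


def to_gray(image: np.ndarray) -> np.ndarray:
    """RGB (or already-gray) raster to float grayscale in [0, 255]."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr @ _LUMA
    return arr


@dataclass
class EdgeMap:
    raster: np.ndarray  # bool, HxW

    @property
    def coordinates(self) -> np.ndarray:
        """Edge pixel coordinates as an (N, 2) array of (x, y), 0-based."""
        ys, xs = np.nonzero(self.raster)
        return np.column_stack([xs, ys])

    @property
    def n_pixels(self) -> int:
        return int(self.raster.sum())


@dataclass
class CircleCandidate:
    center: tuple[float, float]
    radius_px: float
    support_fraction: float = 0.0
    n_support: int = 0  # supporting edge pixels


@dataclass
class DetectedCircle:
    center: tuple[float, float]
    radius_px: float
    support_fraction: float = 0.0
    background_fraction: float = 0.0
    status: str = RETAINED


@dataclass
class DetectorParams:
    """Knobs of the randomized detector and its two screening checks.

    ``radius_sd_multiplier`` = 2 and ``background_fraction_max`` = 0.10
    are the published screening thresholds; the rest are adaptive-rule
    or sampling defaults.
    """

    min_edge_pixels: int = 120
    min_support_fraction: float = 0.6
    sample_budget: int = 20000
    inlier_tolerance_px: float = 1.5
    radius_sd_multiplier: float = 2.0
    background_fraction_max: float = 0.10
    min_radius_px: float = 8.0
    min_arc_run_fraction: float = 0.25  # longest contiguous supported arc
    canny_sigma: float = 1.6
    rng_seed: int = 0

    def validate(self) -> None:
        if not (0 < self.min_support_fraction <= 1):
            raise ValueError("min_support_fraction must be in (0, 1]")
        if self.sample_budget < 1:
            raise ValueError("sample_budget must be >= 1")


def edge_map(image: np.ndarray, sigma: float = 1.6, gain: float = 0.35) -> EdgeMap:
    """Canny edge map with thresholds adapted to the image statistics.

    Hysteresis thresholds are the classic 0.66/1.33 x median-intensity
    rule, mapped onto the gradient-magnitude scale of the smoothed image
    by ``gain`` (full-scene segmentation uses the default; within-seed
    region analysis uses a lower gain for its subtler edges).  A fully
    uniform image yields an empty map.
    """
    gray = to_gray(image)
    if gray.size == 0:
        raise ValueError("empty image")
    if np.ptp(gray) < 1e-9:
        return EdgeMap(np.zeros(gray.shape, dtype=bool))
    med = float(np.median(gray))
    # gradient of a unit-normalized image: scale intensity thresholds to [0,1]
    lo = max(0.66 * med, 8.0) / 255.0
    hi = max(1.33 * med, 16.0) / 255.0
    edges = skfeature.canny(
        gray / 255.0,
        sigma=sigma,
        low_threshold=lo * gain,
        high_threshold=hi * gain,
    )
    return EdgeMap(edges)


def circumcircle(p1, p2, p3) -> CircleCandidate:
    """Circle through three points; raises on (near-)collinear input."""
    (x1, y1), (x2, y2), (x3, y3) = p1, p2, p3
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    if abs(d) < 1e-9:
        raise DegenerateGeometryError("collinear points have no circumcircle")
    s1 = x1 * x1 + y1 * y1
    s2 = x2 * x2 + y2 * y2
    s3 = x3 * x3 + y3 * y3
    ux = (s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)) / d
    uy = (s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)) / d
    r = float(np.hypot(x1 - ux, y1 - uy))
    return CircleCandidate(center=(float(ux), float(uy)), radius_px=r)


def _angular_support(
    pts: np.ndarray, cx: float, cy: float, n_bins: int = 72
) -> tuple[float, float]:
    """Circumference coverage of supporting pixels.

    Returns (fraction of occupied 5-degree angular bins, longest
    contiguous occupied arc as a fraction of the full circle).  The
    second figure separates true rims — supported by extended arcs —
    from spurious circles supported only by scattered edge crossings.
    """
    theta = np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)
    bins = ((theta + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    occupied = np.zeros(n_bins, dtype=bool)
    occupied[bins] = True
    if occupied.all():
        return 1.0, 1.0
    # longest circular run: rotate so a gap is at the boundary
    gap = int(np.argmin(occupied))
    rolled = np.roll(occupied, -gap)
    best = run = 0
    for v in rolled:
        run = run + 1 if v else 0
        best = max(best, run)
    return occupied.mean(), best / n_bins


def _lsq_circle(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit."""
    A = np.column_stack([2 * xs, 2 * ys, np.ones_like(xs)])
    b = xs * xs + ys * ys
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = float(np.sqrt(max(c + cx * cx + cy * cy, 0.0)))
    return float(cx), float(cy), r


def detect_circles(edges: EdgeMap, params: DetectorParams) -> list[CircleCandidate]:
    """Randomized circle detection on an edge map.

    Samples triples of remaining edge pixels, accepts circumcircles whose
    circumference support reaches ``min_support_fraction``, refines each
    acceptance by least-squares on its inliers, removes the inliers, and
    repeats until the sample budget is spent or fewer than
    ``min_edge_pixels`` edge pixels remain.  Deterministic given
    ``rng_seed``.
    """
    params.validate()
    if edges.n_pixels == 0:
        return []
    from scipy.ndimage import binary_dilation
    from skimage.measure import label as sklabel
    from skimage.morphology import disk

    h, w = edges.raster.shape
    max_radius = 0.6 * min(h, w)
    rng = np.random.default_rng(params.rng_seed)
    # group nearby edge fragments into regions: a textured seed's rim may
    # break into several components that still belong to one circle
    groups = sklabel(binary_dilation(edges.raster, structure=disk(2)), connectivity=2)
    labeled = np.where(edges.raster, groups, 0)
    accepted: list[CircleCandidate] = []

    # edge regions are processed independently: triples sampled within one
    # edge region, support counted against that region's pixels
    for region_id in range(1, labeled.max() + 1):
        ys, xs = np.nonzero(labeled == region_id)
        coords = np.column_stack([xs, ys]).astype(np.float64)
        if len(coords) < params.min_edge_pixels:
            continue
        alive = np.ones(len(coords), dtype=bool)
        budget = min(params.sample_budget, 1500)
        misses = 0
        for _ in range(budget):
            alive_idx = np.nonzero(alive)[0]
            if len(alive_idx) < max(params.min_edge_pixels, 3) or misses > 500:
                break
            tri = rng.choice(alive_idx, size=3, replace=False)
            p = coords[tri]
            try:
                cand = circumcircle(p[0], p[1], p[2])
            except DegenerateGeometryError:
                misses += 1
                continue
            if not (params.min_radius_px <= cand.radius_px <= max_radius):
                misses += 1
                continue
            (cx, cy), r = cand.center, cand.radius_px
            d = np.abs(np.hypot(coords[alive_idx, 0] - cx,
                                coords[alive_idx, 1] - cy) - r)
            inliers = alive_idx[d <= params.inlier_tolerance_px]
            if len(inliers) < params.min_edge_pixels:
                misses += 1
                continue
            cov, _run = _angular_support(coords[inliers], cx, cy)
            if cov < params.min_support_fraction:
                misses += 1
                continue
            # iterative sub-pixel refinement with annealed tolerance: the
            # sharply localized rim keeps its support as the band tightens,
            # while fits contaminated by interior texture fall apart
            ok = True
            for tol in (params.inlier_tolerance_px,
                        0.8 * params.inlier_tolerance_px,
                        0.6 * params.inlier_tolerance_px):
                cx, cy, r = _lsq_circle(coords[inliers, 0], coords[inliers, 1])
                if not (params.min_radius_px <= r <= max_radius):
                    ok = False
                    break
                d = np.abs(np.hypot(coords[alive_idx, 0] - cx,
                                    coords[alive_idx, 1] - cy) - r)
                inliers = alive_idx[d <= tol]
                if len(inliers) < 3:
                    ok = False
                    break
            if ok:
                cx, cy, r = _lsq_circle(coords[inliers, 0], coords[inliers, 1])
            if not ok or not (params.min_radius_px <= r <= max_radius):
                misses += 1
                continue
            if len(inliers) < params.min_edge_pixels:
                misses += 1
                continue
            support, run = _angular_support(coords[inliers], cx, cy)
            if support < params.min_support_fraction or run < params.min_arc_run_fraction:
                misses += 1
                continue
            new = CircleCandidate(center=(cx, cy), radius_px=r,
                                  support_fraction=float(support),
                                  n_support=len(inliers))
            # duplicate suppression: merge overlapping acceptances,
            # keeping the circle with the most supporting pixels
            merged = False
            for i, old in enumerate(accepted):
                if np.hypot(old.center[0] - cx,
                            old.center[1] - cy) < 0.5 * old.radius_px:
                    if (new.n_support, new.support_fraction) > (
                            old.n_support, old.support_fraction):
                        accepted[i] = new
                    merged = True
                    break
            if not merged:
                accepted.append(new)
            alive[inliers] = False
            misses = 0

    return accepted


def radius_filter(
    circles: list[DetectedCircle], multiplier: float = 2.0
) -> list[DetectedCircle]:
    """Per-image statistical screen: flag radii outside mean +/- k*SD.

    Mean and standard deviation are those of all detected radii in the
    image.  Note the screen's known blind spot: a single gross outlier
    inflates the very sigma it is judged by and can evade a 2-sigma
    band; it is still caught downstream by the radiometric check.  A
    single circle is retained unconditionally (no spread estimate from
    one sample).
    """
    if not circles:
        raise ValueError("radius_filter requires at least one circle")
    radii = np.array([c.radius_px for c in circles])
    if len(circles) == 1:
        return [replace(circles[0])]
    mu, sd = float(radii.mean()), float(radii.std())
    out = []
    for c in circles:
        if abs(c.radius_px - mu) > multiplier * sd:
            out.append(replace(c, status=DISCARDED_RADIUS))
        else:
            out.append(replace(c))
    return out


def _interior_mask(shape, center, radius):
    h, w = shape
    cx, cy = center
    x0, x1 = int(np.floor(cx - radius)), int(np.ceil(cx + radius)) + 1
    y0, y1 = int(np.floor(cy - radius)), int(np.ceil(cy + radius)) + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return None, None
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius * radius
    return (slice(y0c, y1c), slice(x0c, x1c)), mask


def background_level_threshold(gray: np.ndarray) -> float:
    """Gray level separating the dark surface from seed material.

    Otsu's split isolates the dark class (the surface); the working
    threshold is the dark-class median plus five robust sigmas (from the
    median absolute deviation), capped at the Otsu value.  Genuinely
    dark seed markings therefore stay on the seed side while the
    surface, whatever its texture, stays background.
    """
    t0 = float(threshold_otsu(gray))
    dark = gray[gray < t0]
    if dark.size == 0:
        return t0
    m_bg = float(np.median(dark))
    sigma = 1.4826 * float(np.median(np.abs(dark - m_bg)))
    return min(m_bg + max(5.0 * sigma, 10.0), t0)


def radiometric_filter(
    circle: DetectedCircle,
    image: np.ndarray,
    max_bg: float = 0.10,
    background_threshold: float | None = None,
) -> DetectedCircle:
    """Flag circles whose interior holds too many dark background pixels.

    The background threshold starts from Otsu's split of the grayscale
    image (dark surface vs bright seeds) and is anchored near the dark
    class center, so dark pattern markings on a seed do not count as
    background.  Fraction above ``max_bg`` marks the circle discarded.
    """
    gray = to_gray(image)
    window, mask = _interior_mask(gray.shape, circle.center, circle.radius_px)
    if window is None or not mask.any():
        raise ValueError("circle interior lies fully outside the image")
    if background_threshold is None:
        background_threshold = background_level_threshold(gray)
    interior = gray[window][mask]
    bg_frac = float(np.mean(interior < background_threshold))
    status = DISCARDED_RADIOMETRIC if bg_frac > max_bg else circle.status
    return replace(circle, background_fraction=bg_frac, status=status)


@dataclass
class SeedPatch:
    """Square crop around a detected circle plus its disc-interior mask."""

    pixels: np.ndarray  # HxWx3 uint8
    mask: np.ndarray  # HxW bool
    source_image: str = ""
    source_circle: DetectedCircle | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != self.mask.shape:
            raise ValueError("pixels and mask dimensions differ")
        if not self.mask.any():
            raise ValueError("empty patch mask")


def extract_patch(
    image: np.ndarray, circle: DetectedCircle, source_image: str = ""
) -> SeedPatch:
    """Square crop of side 2*radius centered on the circle.

    Crops falling over the image border are clipped and flagged; the
    circular mask stays consistent with the crop geometry.
    """
    arr = np.asarray(image)
    h, w = arr.shape[:2]
    cx, cy = circle.center
    r = circle.radius_px
    x0, x1 = int(round(cx - r)), int(round(cx + r))
    y0, y1 = int(round(cy - r)), int(round(cy + r))
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    clipped = (x0c, x1c, y0c, y1c) != (x0, x1, y0, y1)
    crop = arr[y0c:y1c, x0c:x1c]
    yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    return SeedPatch(pixels=crop, mask=mask, source_image=source_image,
                     source_circle=circle, clipped=clipped)
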