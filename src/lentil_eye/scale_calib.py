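"""Scale calibration from an in-frame graph-paper strip.

The millimetre squares of the strip are detected as 4-vertex contour
polygons; the modal side length in pixels (EDV) against the known
square side in mm (ADV) gives the scale factor S = ADV / EDV.  Seed
sizes in mm follow by converting the mean detected radius.

Note on units: the published worked example converts a 146 px mean
radius at 56.64 px/mm into a 5.16 mm "size" — arithmetic that only
holds for the diameter (2 * 146 / 56.64).  The reported seed size here
is therefore the diameter in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from lentil_eye.circle_detect import to_gray


class CalibrationUnavailableError(RuntimeError):
    """No (or too few) graph-paper squares visible in the image."""


@dataclass
class SquareDetection:
    contour: np.ndarray  # (4, 2) polygon vertices, (x, y)
    side_lengths_px: tuple[float, float, float, float]

    @property
    def mean_side_px(self) -> float:
        return float(np.mean(self.side_lengths_px))


@dataclass
class ScaleEstimate:
    EDV: float  # estimated average square side, pixels
    ADV: float  # known square side, mm
    n_squares: int
    side_histogram: tuple[np.ndarray, np.ndarray]  # (bin_edges, counts)

    @property
    def S(self) -> float:
        """Scale factor, mm per pixel."""
        return self.ADV / self.EDV

    @property
    def px_per_mm(self) -> float:
        return self.EDV / self.ADV


def _polygon_sides(poly: np.ndarray) -> np.ndarray:
    nxt = np.roll(poly, -1, axis=0)
    return np.hypot(*(nxt - poly).T)


def _corner_cosines(poly: np.ndarray) -> np.ndarray:
    prv = np.roll(poly, 1, axis=0)
    nxt = np.roll(poly, -1, axis=0)
    u = prv - poly
    v = nxt - poly
    num = np.abs((u * v).sum(axis=1))
    den = np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    return num / np.maximum(den, 1e-12)


def locate_strip(image: np.ndarray) -> tuple[int, int, int, int]:
    """Auto-locate the graph-paper strip as the brightest contiguous rows.

    Returns an (x, y, w, h) ROI.  Falls back to the full image if no
    clearly bright band exists.
    """
    gray = to_gray(image)
    row_mean = gray.mean(axis=1)
    thr = 0.5 * (row_mean.min() + row_mean.max())
    bright = row_mean > thr
    if not bright.any():
        return (0, 0, gray.shape[1], gray.shape[0])
    # bridge the dark horizontal grid lines that interrupt the paper rows
    from scipy.ndimage import binary_closing as close1d

    bright = close1d(bright, structure=np.ones(5))
    # largest contiguous run of bright rows
    padded = np.diff(np.concatenate([[0], bright.astype(int), [0]]))
    starts, ends = np.nonzero(padded == 1)[0], np.nonzero(padded == -1)[0]
    i = int(np.argmax(ends - starts))
    return (0, int(starts[i]), gray.shape[1], int(ends[i] - starts[i]))


def detect_squares(
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    min_side_px: float = 3.0,
    line_width_px: float = 1.0,
) -> list[SquareDetection]:
    """Find graph-paper squares as near-square 4-vertex contour polygons.

    The grid cells (light paper bounded by dark lines) are thresholded,
    their closed contours followed and approximated to polygons; only
    4-vertex polygons with near-equal sides and near-right angles are
    kept.  Raises if no square can be found.
    """
    gray = to_gray(image)
    if roi is None:
        roi = locate_strip(image)
    x, y, w, h = roi
    sub = gray[y : y + h, x : x + w]
    if sub.size == 0 or np.ptp(sub) < 1e-9:
        raise CalibrationUnavailableError("no graph-paper squares visible")
    thr = threshold_otsu(sub)
    cells = sub > thr
    labeled = measure.label(cells, connectivity=1)
    squares: list[SquareDetection] = []
    for region in measure.regionprops(labeled):
        if region.area < min_side_px * min_side_px:
            continue
        r0, c0, r1, c1 = region.bbox
        if r0 == 0 or c0 == 0 or r1 == labeled.shape[0] or c1 == labeled.shape[1]:
            continue  # cell cut off at the ROI border
        tile = np.pad(region.image, 1)
        contours = measure.find_contours(tile.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        # squareness screen on the simplified contour polygon
        poly = measure.approximate_polygon(contour, tolerance=1.4)
        if len(poly) > 1 and np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        if len(poly) != 4:
            continue
        # corner vertices from diagonal extremes (immune to corner-cutting)
        s = contour.sum(axis=1)
        dterm = contour[:, 0] - contour[:, 1]
        corners = contour[[np.argmin(s), np.argmax(dterm), np.argmax(s),
                           np.argmin(dterm)]]
        # contour coords are (row, col) in the padded tile; convert to image (x, y)
        xy = np.column_stack([corners[:, 1] + c0 - 1 + x,
                              corners[:, 0] + r0 - 1 + y])
        # cell interiors exclude the bounding grid lines: the true square
        # side runs line-center to line-center, hence the +line_width.
        # Side lengths come from the contour extents (the corner-cutting
        # marching-squares diagonals would bias polygon sides low).
        height = float(np.ptp(contour[:, 0]))
        width = float(np.ptp(contour[:, 1]))
        sides = np.array([width, height, width, height]) + line_width_px
        if sides.min() < min_side_px:
            continue
        if sides.max() / sides.min() > 1.3:
            continue
        if (_corner_cosines(xy) >= 0.3).any():
            continue
        squares.append(SquareDetection(contour=xy, side_lengths_px=tuple(sides)))
    if not squares:
        raise CalibrationUnavailableError("no graph-paper squares visible")
    return squares


def estimate_edv(
    squares: list[SquareDetection],
    adv_mm: float = 1.0,
    bin_width_px: float = 1.0,
    quorum: int = 10,
) -> ScaleEstimate:
    """Estimate the average square side from the side-length histogram.

    All side lengths are binned at ``bin_width_px``; EDV is the mean of
    sides falling in the modal bin +/- one bin, which rejects outlier
    contours.  Raises if fewer than ``quorum`` squares are available.
    """
    if len(squares) < quorum:
        raise CalibrationUnavailableError(
            f"calibration quorum not met: {len(squares)} squares < {quorum}"
        )
    sides = np.concatenate([np.asarray(s.side_lengths_px) for s in squares])
    lo = np.floor(sides.min())
    hi = np.ceil(sides.max()) + bin_width_px
    edges = np.arange(lo, hi + bin_width_px, bin_width_px)
    counts, edges = np.histogram(sides, bins=edges)
    k = int(np.argmax(counts))
    keep = (sides >= edges[max(k - 1, 0)]) & (sides < edges[min(k + 2, len(edges) - 1)])
    edv = float(sides[keep].mean())
    return ScaleEstimate(EDV=edv, ADV=adv_mm, n_squares=len(squares),
                         side_histogram=(edges, counts))


def calibrate(
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    adv_mm: float = 1.0,
    quorum: int = 10,
) -> ScaleEstimate:
    """Detect squares and estimate the scale in one call."""
    return estimate_edv(detect_squares(image, roi=roi), adv_mm=adv_mm, quorum=quorum)


def seed_size_mm(mean_radius_px: float, scale: ScaleEstimate) -> float:
    """Seed size (diameter) in mm from the mean detected radius in px."""
    if mean_radius_px <= 0:
        raise ValueError("mean_radius_px must be positive")
    if scale is None:
        raise ValueError("missing calibration")
    return 2.0 * mean_radius_px * scale.S


def absolute_error(measured_mm: float, estimated_mm: float) -> float:
    """|measured - estimated|."""
    if measured_mm < 0 or estimated_mm < 0:
        raise ValueError("sizes must be non-negative")
    return abs(measured_mm - estimated_mm)


def truncate(value: float, places: int) -> float:
    """Truncate toward zero at the given decimal place.

    Presentation helper for printed scale factors, which by convention
    drop (rather than round) trailing digits: 1/56.64 prints as 0.01765.
    """
    factor = 10.0 ** places
    return math.trunc(value * factor) / factor
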