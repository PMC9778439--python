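"""Synthetic seed scenes and labeled patches with known ground truth.

Renders the kind of photograph the pipeline expects — bright roughly
circular seeds on a dark surface with a millimetre graph-paper strip
across the top — plus single-seed patches carrying one of the five testa
pattern textures. Every render is deterministic given its seed, so the
generator doubles as the test oracle for the detection, calibration and
classification stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

PATTERN_CLASSES = ("absent", "dotted", "spotted", "marbled", "complex")

#: fixed pattern-class -> texture-group mapping
TEXTURE_GROUP = {
    "absent": "rare",
    "spotted": "rare",
    "dotted": "sparse",
    "complex": "sparse",
    "marbled": "dense",
}

# Texture generator constants.  Chosen so the five classes measurably
# satisfy their verbal definitions: spotted = 1-4 localized blobs,
# dotted = many small dots totalling < 50% of the disc, complex =
# spread patches covering > 50%, marbled = whole-surface stain field.
SPOT_BLOB_RADIUS = (0.10, 0.18)   # fraction of disc radius
SPOT_BLOB_COUNT = (1, 4)
DOT_RADIUS = (0.050, 0.075)       # fraction of disc radius
DOT_COUNT = (40, 55)
COMPLEX_COVERAGE = (0.70, 0.82)
MARBLE_SIGMA_FRACTION = 6         # patch_size / this = stain smoothness
NOISE_SIGMA = 4.0                 # additive gaussian pixel noise, gray levels

STRIP_PAPER_LEVEL = 235
STRIP_LINE_LEVEL = 110


class PlacementError(RuntimeError):
    """Raised when non-overlapping seed placement fails after bounded retries."""


@dataclass(frozen=True)
class PatternClass:
    """One of the five canonical testa-pattern classes."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in PATTERN_CLASSES:
            raise ValueError(f"unknown pattern class: {self.value!r}")

    @property
    def texture_group(self) -> str:
        return TEXTURE_GROUP[self.value]


@dataclass
class SceneSpec:
    """Parameters of a rendered seed scene."""

    image_size: tuple[int, int] = (900, 700)  # (width, height)
    n_seeds: int = 10
    radius_range_px: tuple[float, float] = (40.0, 60.0)
    px_per_mm: float = 20.0
    strip_height_px: int = 80
    background_level: int = 30
    seed_base_color: tuple[int, int, int] = (205, 160, 120)
    overlap_allowed: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.radius_range_px[0] < 5:
            raise ValueError("minimum seed radius must be >= 5 px")
        if self.radius_range_px[1] < self.radius_range_px[0]:
            raise ValueError("radius range must be (min, max)")
        if self.px_per_mm <= 2:
            raise ValueError("px_per_mm must exceed 2 for resolvable squares")
        if not (0 <= self.background_level < 80):
            raise ValueError("background_level must be in [0, 80) (dark surface)")
        if self.n_seeds < 0:
            raise ValueError("n_seeds must be >= 0")


@dataclass
class SceneTruth:
    """Ground truth for a rendered scene."""

    circles: list[tuple[float, float, float]]  # (center_x, center_y, radius_px)
    px_per_mm: float
    patch_labels: list[PatternClass] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "circles": [list(c) for c in self.circles],
                "px_per_mm": self.px_per_mm,
                "patch_labels": [p.value for p in self.patch_labels],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SceneTruth":
        d = json.loads(text)
        return cls(
            circles=[tuple(c) for c in d["circles"]],
            px_per_mm=d["px_per_mm"],
            patch_labels=[PatternClass(v) for v in d["patch_labels"]],
        )


def _disc_alpha(size: int, cx: float, cy: float, r: float) -> np.ndarray:
    """Anti-aliased disc coverage: 1 inside, 0 outside, linear ramp at rim."""
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.hypot(xx - cx, yy - cy)
    return np.clip(r + 0.5 - d, 0.0, 1.0)


def _pattern_layers(
    cls: PatternClass,
    size: int,
    rng: np.random.Generator,
    base: np.ndarray,
    radius: float | None = None,
) -> tuple[np.ndarray, float]:
    """Render a noiseless pattern patch (float RGB) plus its true coverage.

    Coverage is the fraction of the disc genuinely occupied by pattern
    foreground (0 for absent/marbled which have no discrete foreground).
    """
    r = size / 2.0 - 2.0 if radius is None else radius
    c = (size - 1) / 2.0
    img = np.zeros((size, size, 3), dtype=np.float64)
    disc = _disc_alpha(size, c, c, r)
    disc_area = float(np.sum(disc > 0.5))
    for ch in range(3):
        img[..., ch] = disc * base[ch]

    dark = base * 0.45
    coverage = 0.0

    if cls.value == "absent":
        pass
    elif cls.value == "spotted":
        n_blobs = int(rng.integers(SPOT_BLOB_COUNT[0], SPOT_BLOB_COUNT[1] + 1))
        for _ in range(n_blobs):
            rho = rng.uniform(0.0, 0.55) * r
            theta = rng.uniform(0.0, 2 * np.pi)
            bx, by = c + rho * np.cos(theta), c + rho * np.sin(theta)
            br = rng.uniform(*SPOT_BLOB_RADIUS) * r
            a = _disc_alpha(size, bx, by, br) * (disc > 0.5)
            for ch in range(3):
                img[..., ch] = img[..., ch] * (1 - a) + a * dark[ch]
            coverage += np.pi * br * br / disc_area
    elif cls.value == "dotted":
        n_dots = int(rng.integers(DOT_COUNT[0], DOT_COUNT[1] + 1))
        fg = np.zeros((size, size), dtype=np.float64)
        for _ in range(n_dots):
            rho = np.sqrt(rng.uniform(0.0, 1.0)) * (r * 0.88)
            theta = rng.uniform(0.0, 2 * np.pi)
            dx, dy = c + rho * np.cos(theta), c + rho * np.sin(theta)
            dr = rng.uniform(*DOT_RADIUS) * r
            fg = np.maximum(fg, _disc_alpha(size, dx, dy, dr))
        fg *= disc > 0.5
        for ch in range(3):
            img[..., ch] = img[..., ch] * (1 - fg) + fg * dark[ch]
        coverage = float(np.sum(fg > 0.5)) / disc_area
    elif cls.value == "complex":
        target = rng.uniform(*COMPLEX_COVERAGE)
        noise = rng.standard_normal((size, size))
        fieldmap = gaussian_filter(noise, sigma=size / 18.0)
        inside = disc > 0.5
        thr = np.quantile(fieldmap[inside], 1.0 - target)
        fg = ((fieldmap >= thr) & inside).astype(np.float64)
        fg = np.clip(gaussian_filter(fg, sigma=0.8) * 1.4, 0, 1) * inside
        # patterns fade smoothly toward the rim (convex seeds show a clean
        # rim band); the gradual taper adds no concentric edge of its own
        yy, xx = np.mgrid[0:size, 0:size]
        dist = np.hypot(xx - c, yy - c)
        ramp = max(8.0, 0.16 * r)
        fg *= np.clip((r - 2.0 - dist) / ramp, 0.0, 1.0)
        # mottle the patch interiors so the pattern is texture-rich, not
        # flat, while its darkest points stay clearly brighter than the
        # dark surface (brightness factor >= 0.42)
        mottle = np.clip(
            gaussian_filter(rng.standard_normal((size, size)), sigma=2.0) * 1.6,
            -1.0, 1.0)
        shade = 1 - fg * np.clip(0.38 - 0.20 * mottle, 0.18, 0.58)
        for ch in range(3):
            img[..., ch] *= shade
        coverage = float(np.sum(fg > 0.5)) / disc_area
    elif cls.value == "marbled":
        low = gaussian_filter(rng.standard_normal((size, size)),
                              sigma=size / MARBLE_SIGMA_FRACTION)
        mid = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 16.0)
        fieldmap = low + 0.5 * mid
        lo, hi = fieldmap.min(), fieldmap.max()
        fieldmap = (fieldmap - lo) / max(hi - lo, 1e-12)
        shade = 0.50 + 0.55 * fieldmap
        for ch in range(3):
            img[..., ch] *= shade
        coverage = 0.0
    return img, coverage


def generate_patch(
    cls: PatternClass,
    size_px: int,
    rng_seed: int,
    *,
    base_color: tuple[int, int, int] = (205, 160, 120),
    with_info: bool = False,
):
    """Render a single-seed patch of the given pattern class.

    Returns ``(patch, mask)`` where ``patch`` is an RGB uint8 raster of
    side ``size_px`` and ``mask`` is the boolean disc interior.  With
    ``with_info=True`` a third dict holds the true foreground coverage.
    """
    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    if not isinstance(cls, PatternClass):
        cls = PatternClass(cls)
    rng = np.random.default_rng(rng_seed)
    base = np.asarray(base_color, dtype=np.float64) * rng.uniform(0.92, 1.08)
    img, coverage = _pattern_layers(cls, size_px, rng, base)
    img += rng.normal(0.0, NOISE_SIGMA, size=img.shape)
    patch = np.clip(img, 0, 255).astype(np.uint8)
    r = size_px / 2.0 - 2.0
    c = (size_px - 1) / 2.0
    mask = _disc_alpha(size_px, c, c, r) > 0.5
    if with_info:
        return patch, mask, {"coverage": coverage, "class": cls.value}
    return patch, mask


def _render_strip(img: np.ndarray, spec: SceneSpec) -> None:
    """Paint the graph-paper strip: dark 1-px grid lines on light ground."""
    h = spec.strip_height_px
    img[:h, :, :] = STRIP_PAPER_LEVEL
    pitch = spec.px_per_mm
    width = img.shape[1]
    for k in range(int(width / pitch) + 1):
        x = int(round(k * pitch))
        if x < width:
            img[:h, x, :] = STRIP_LINE_LEVEL
    for k in range(int(h / pitch) + 1):
        y = int(round(k * pitch))
        if y < h:
            img[y, :, :] = STRIP_LINE_LEVEL


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render a full scene and its ground truth.

    The image holds ``n_seeds`` textured anti-aliased discs on the dark
    surface plus the graph-paper strip across the top; identical specs
    produce bit-identical images.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    width, height = spec.image_size
    img = np.full((height, width, 3), float(spec.background_level))
    _render_strip(img, spec)

    r_min, r_max = spec.radius_range_px
    margin = 4.0
    placed: list[tuple[float, float, float]] = []
    labels: list[PatternClass] = []
    max_tries = 300 * max(spec.n_seeds, 1)
    tries = 0
    while len(placed) < spec.n_seeds:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {spec.n_seeds} non-overlapping seeds "
                f"after {max_tries} attempts"
            )
        tries += 1
        r = rng.uniform(r_min, r_max)
        cx = rng.uniform(r + margin, width - r - margin)
        cy = rng.uniform(spec.strip_height_px + r + margin, height - r - margin)
        if not spec.overlap_allowed and any(
            np.hypot(cx - px, cy - py) < r + pr + margin for px, py, pr in placed
        ):
            continue
        placed.append((cx, cy, r))
        labels.append(PatternClass(rng.choice(PATTERN_CLASSES)))

    true_circles: list[tuple[float, float, float]] = []
    for (cx, cy, r), cls in zip(placed, labels):
        size = int(np.ceil(2 * r)) + 6
        sub_rng = np.random.default_rng(int(rng.integers(0, 2**31)))
        base = np.asarray(spec.seed_base_color, np.float64) * sub_rng.uniform(0.92, 1.08)
        tile, _ = _pattern_layers(cls, size, sub_rng, base, radius=r)
        c = (size - 1) / 2.0
        alpha = _disc_alpha(size, c, c, r)
        x0 = int(round(cx - c))
        y0 = int(round(cy - c))
        ys = slice(max(y0, 0), min(y0 + size, height))
        xs = slice(max(x0, 0), min(x0 + size, width))
        ty = slice(ys.start - y0, ys.stop - y0)
        tx = slice(xs.start - x0, xs.stop - x0)
        a = alpha[ty, tx][..., None]
        img[ys, xs, :] = img[ys, xs, :] * (1 - a) + tile[ty, tx, :] * a
        true_circles.append((x0 + c, y0 + c, float(r)))

    img += rng.normal(0.0, NOISE_SIGMA, size=img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)
    truth = SceneTruth(circles=true_circles, px_per_mm=float(spec.px_per_mm),
                       patch_labels=labels)
    return image, truth


def write_scene(out_dir: str | Path, name: str, image: np.ndarray,
                truth: SceneTruth) -> tuple[Path, Path]:
    """Write a scene PNG and its JSON truth sidecar."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    png = out / f"{name}.png"
    js = out / f"{name}.truth.json"
    iio.imwrite(png, image)
    js.write_text(truth.to_json())
    return png, js
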