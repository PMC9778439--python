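import numpy as np
import pytest

from lentil_eye.circle_detect import SeedPatch
from lentil_eye.synthetic_scene import (
    PATTERN_CLASSES,
    PatternClass,
    SceneSpec,
    generate_patch,
    generate_scene,
)
from lentil_eye.texture_classify import TrainConfig, train
from lentil_eye.texture_features import feature_vector


def make_patch(cls: str, seed: int, size: int = 100) -> SeedPatch:
    pixels, mask = generate_patch(PatternClass(cls), size, seed)
    return SeedPatch(pixels=pixels, mask=mask)


def patch_features(cls: str, seeds, size: int = 100):
    return [feature_vector(make_patch(cls, s, size)) for s in seeds]


def grid_oracle(coords, center, radius, span=2.0, step=0.25, tol=1.5):
    """Exhaustive Hough-style circle search near a reference circle.

    Maximizes the supporting-pixel count over a (center +/- span,
    radius +/- span) grid; ties broken by the RMS ring residual so the
    optimum is well localized on the support plateau.
    """
    best, best_key = None, None
    for cx in np.arange(center[0] - span, center[0] + span + 1e-9, step):
        for cy in np.arange(center[1] - span, center[1] + span + 1e-9, step):
            d = np.hypot(coords[:, 0] - cx, coords[:, 1] - cy)
            for r in np.arange(radius - span, radius + span + 1e-9, step):
                res = np.abs(d - r)
                inl = res <= tol
                n = int(inl.sum())
                rms = float(np.sqrt(np.mean(res[inl] ** 2))) if n else np.inf
                key = (-n, rms)
                if best_key is None or key < best_key:
                    best, best_key = (cx, cy, r), key
    return best


@pytest.fixture(scope="session")
def scene10():
    """A 10-seed scene with truth, reused across detection tests."""
    return generate_scene(SceneSpec(n_seeds=10, rng_seed=7))


@pytest.fixture(scope="session")
def texture_model():
    """3-class model trained on 30 patches per pattern class (seeds 1000+)."""
    feats, groups = [], []
    for cls in PATTERN_CLASSES:
        for s in range(30):
            feats.append(feature_vector(make_patch(cls, 1000 + hash(cls) % 997 + s)))
            groups.append(PatternClass(cls).texture_group)
    return train(feats, groups, TrainConfig(rng_seed=0))
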