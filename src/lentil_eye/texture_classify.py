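"""Three-class texture classifier (rare / sparse / dense).

A gradient-boosted decision-tree ensemble with a multi-class softmax
objective maps 198-dim feature vectors to texture groups.  Evaluation
follows the leave-one-out protocol, with grouped and k-fold variants
for larger runs.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier

from lentil_eye.metrics import ConfusionMatrix, confusion
from lentil_eye.texture_features import N_FEATURES, FeatureVector

TEXTURE_LABELS = ("rare", "sparse", "dense")


@dataclass
class TrainConfig:
    max_depth: int = 4
    n_rounds: int = 200
    learning_rate: float = 0.1
    rng_seed: int = 0
    class_weight: dict[str, float] | None = None

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "max_depth": self.max_depth,
                "n_rounds": self.n_rounds,
                "learning_rate": self.learning_rate,
                "rng_seed": self.rng_seed,
                "class_weight": self.class_weight,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_matrix(features) -> np.ndarray:
    rows = []
    for f in features:
        vec = f.combined if isinstance(f, FeatureVector) else np.asarray(f, float)
        if vec.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have {N_FEATURES} entries")
        rows.append(vec)
    return np.vstack(rows)


@dataclass
class TrainedModel:
    """Fitted ensemble plus the metadata needed for reproducible use."""

    estimator: GradientBoostingClassifier
    class_order: tuple[str, ...]
    config: TrainConfig
    n_features: int = N_FEATURES

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        return self.estimator.predict_proba(X)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.write_bytes(pickle.dumps(self))
        meta = {
            "class_order": list(self.class_order),
            "n_features": self.n_features,
            "config_fingerprint": self.config.fingerprint(),
            "rng_seed": self.config.rng_seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        obj = pickle.loads(Path(path).read_bytes())
        if not isinstance(obj, cls):
            raise TypeError("file does not hold a TrainedModel")
        return obj


def train(features, labels, config: TrainConfig | None = None) -> TrainedModel:
    """Fit the boosted ensemble; deterministic given ``config.rng_seed``."""
    config = config or TrainConfig()
    X = _as_matrix(features)
    y = np.asarray([str(l) for l in labels])
    if len(X) != len(y):
        raise ValueError("features and labels must align")
    present = [c for c in TEXTURE_LABELS if c in set(y)]
    extra = sorted(set(y) - set(TEXTURE_LABELS))
    class_order = tuple(present + extra)
    if len(class_order) < 2:
        raise ValueError("degenerate training set: fewer than 2 classes present")
    est = GradientBoostingClassifier(
        n_estimators=config.n_rounds,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        random_state=config.rng_seed,
    )
    sample_weight = None
    if config.class_weight:
        sample_weight = np.array([config.class_weight.get(c, 1.0) for c in y])
    est.fit(X, y, sample_weight=sample_weight)
    return TrainedModel(estimator=est, class_order=class_order, config=config)


def predict(model: TrainedModel, feature) -> str:
    """Arg-max class; ties broken by fixed class order (rare < sparse < dense)."""
    return predict_batch(model, [feature])[0]


def predict_batch(model: TrainedModel, features) -> list[str]:
    X = _as_matrix(features)
    proba = model.predict_scores(X)
    fitted = list(model.estimator.classes_)
    # re-order scores by the model's fixed class order for tie-breaking
    order = [fitted.index(c) for c in model.class_order if c in fitted]
    names = [fitted[i] for i in order]
    scores = proba[:, order]
    best = np.argmax(scores, axis=1)  # first max wins -> fixed-order tie-break
    return [names[i] for i in best]


def loo_evaluate(
    features,
    labels,
    config: TrainConfig | None = None,
    mode: str = "loo",
    k: int = 10,
    groups=None,
) -> ConfusionMatrix:
    """Cross-validated evaluation accumulating a confusion matrix.

    ``mode='loo'`` re-fits once per sample (the fidelity protocol);
    ``mode='kfold'`` uses stratified k folds; ``mode='group'`` leaves one
    group (e.g. one source image) out per fold.  The protocol actually
    used is recorded in the matrix metadata, as are classes that were
    absent from some training fold.
    """
    from sklearn.model_selection import LeaveOneGroupOut, LeaveOneOut, StratifiedKFold

    config = config or TrainConfig()
    X = _as_matrix(features)
    y = np.asarray([str(l) for l in labels])
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if mode == "loo":
        splits = LeaveOneOut().split(X)
    elif mode == "kfold":
        splits = StratifiedKFold(
            n_splits=k, shuffle=True, random_state=config.rng_seed
        ).split(X, y)
    elif mode == "group":
        if groups is None:
            raise ValueError("mode='group' requires groups")
        splits = LeaveOneGroupOut().split(X, y, groups=np.asarray(groups))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    class_names = [c for c in TEXTURE_LABELS if c in set(y)] + sorted(
        set(y) - set(TEXTURE_LABELS)
    )
    y_pred = np.empty_like(y)
    missing_class_folds = 0
    for train_idx, test_idx in splits:
        if len(set(y[train_idx])) < len(class_names):
            missing_class_folds += 1
        model = train(X[train_idx], y[train_idx], config)
        y_pred[test_idx] = predict_batch(model, X[test_idx])
    cm = confusion(list(y), list(y_pred), class_names)
    cm.metadata = {"protocol": mode, "k": k if mode == "kfold" else None,
                   "folds_missing_a_class": missing_class_folds}
    return cm
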