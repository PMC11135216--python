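"""Random-forest behavior classifier.

The model is a standard bagged forest over the 24 window features:
100 trees, unlimited depth, bootstrap sampling, and ``floor(log2(F) + 1)``
candidate features per split (5 for F = 24) — the stock configuration of
classic machine-learning workbenches, kept here as the default and fully
overridable.

Labels are encoded as integers in the canonical fine-class order before
fitting, so equal-vote ties resolve to the earlier class in that order and
predictions are deterministic given (model, input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .exceptions import DataError, FormatError
from .taxonomy import FINE_CLASSES
from .windowing import FEATURE_NAMES

MODEL_MAGIC = "actithigh-forest"
MODEL_VERSION = 1

DEFAULT_N_TREES = 100


def default_max_features(n_features: int) -> int:
    """Per-split feature subsample size: floor(log2(F) + 1)."""
    return int(np.floor(np.log2(n_features) + 1))


@dataclass
class ForestModel:
    """A fitted forest plus the metadata needed to refuse mismatched inputs."""

    estimator: RandomForestClassifier
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    seed: int
    n_trees: int
    max_features: int
    class_order: tuple[str, ...] = field(default=FINE_CLASSES)

    def _check_features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or (len(X) and X.shape[1] != len(self.feature_names)):
            raise ValueError(
                f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns; "
                f"model expects {len(self.feature_names)}"
            )
        return X


def train(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_trees: int = DEFAULT_N_TREES,
    max_features: int | None = None,
    class_order: tuple[str, ...] = FINE_CLASSES,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> ForestModel:
    """Fit a forest on labeled windows. Reproducible for a fixed seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != len(feature_names):
        raise ValueError(f"feature matrix must have {len(feature_names)} columns")
    if len(X) != len(y):
        raise ValueError("feature matrix and label vector lengths differ")
    if len(X) < 10:
        raise ValueError("need at least 10 training rows")
    if not np.all(np.isfinite(X)):
        raise DataError("feature matrix contains non-finite values")
    present = [c for c in class_order if c in set(y)]
    if len(present) < 2:
        raise ValueError("training data must contain at least 2 classes")
    unknown = set(y) - set(class_order)
    if unknown:
        raise ValueError(f"labels outside the class order: {sorted(unknown)}")
    # integer codes in canonical order => sklearn's tie-break (lowest class)
    # becomes "earliest class in canonical order"
    code = {c: i for i, c in enumerate(present)}
    y_enc = np.array([code[v] for v in y])
    mf = default_max_features(X.shape[1]) if max_features is None else max_features
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=min(mf, X.shape[1]),
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(X, y_enc)
    return ForestModel(
        estimator=est,
        classes=tuple(present),
        feature_names=tuple(feature_names),
        seed=seed,
        n_trees=n_trees,
        max_features=min(mf, X.shape[1]),
        class_order=tuple(class_order),
    )


def predict(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """One class label per row; empty input gives an empty vector."""
    X = model._check_features(X)
    if len(X) == 0:
        return np.array([], dtype=object)
    codes = model.estimator.predict(X)
    return np.array([model.classes[int(c)] for c in codes], dtype=object)


def save_model(model: ForestModel, path: str | Path) -> None:
    payload = {
        "magic": MODEL_MAGIC,
        "version": MODEL_VERSION,
        "classes": model.classes,
        "class_order": model.class_order,
        "feature_names": model.feature_names,
        "seed": model.seed,
        "n_trees": model.n_trees,
        "max_features": model.max_features,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> ForestModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:  # truncated/corrupt pickle
        raise FormatError(f"{path}: not a readable model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("magic") != MODEL_MAGIC:
        raise FormatError(f"{path}: not an {MODEL_MAGIC} model file")
    if payload.get("version") != MODEL_VERSION:
        raise FormatError(
            f"{path}: model version {payload.get('version')} != supported {MODEL_VERSION}"
        )
    return ForestModel(
        estimator=payload["estimator"],
        classes=tuple(payload["classes"]),
        feature_names=tuple(payload["feature_names"]),
        seed=payload["seed"],
        n_trees=payload["n_trees"],
        max_features=payload["max_features"],
        class_order=tuple(payload["class_order"]),
    )
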