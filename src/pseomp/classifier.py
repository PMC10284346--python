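"""RBF-kernel support vector machine over Pse-AAC feature matrices.

The kernel is K(x_i, x_j) = exp(−γ‖x_i − x_j‖²) with width γ and
regularization cost C.  Training is deterministic (no subsampling), the
decision score is oriented so that a higher value is more OMP-like, and
a score of exactly 0 is classified negative.

Pse-AAC components already live in [0, 1] and sum to one, so no feature
scaling is applied by default; an optional per-feature min–max scaler
can be fitted on the training data (and only there, to avoid leakage).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
from sklearn.svm import SVC

from . import __version__
from .pseaac import PseAACConfig


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters."""

    gamma: float = 0.07
    cost: float = 32.0

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not self.cost > 0:
            raise ValueError(f"cost must be > 0, got {self.cost}")


@dataclass
class TrainedModel:
    """Fitted SVM plus the configuration that produced it."""

    svc: SVC
    svm_config: SVMConfig
    pse_config: Optional[PseAACConfig] = None
    scaler_min: Optional[np.ndarray] = None
    scaler_range: Optional[np.ndarray] = None

    @property
    def n_features(self) -> int:
        return int(self.svc.n_features_in_)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"dimensionality mismatch: model expects {self.n_features} "
                f"features, got {X.shape[1]}"
            )
        if X.size and not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        if self.scaler_min is not None:
            X = (X - self.scaler_min) / self.scaler_range
        return X


def train(
    features: np.ndarray,
    labels: np.ndarray,
    config: SVMConfig,
    *,
    pse_config: Optional[PseAACConfig] = None,
    scale: bool = False,
    class_weight: Optional[str] = None,
) -> TrainedModel:
    """Fit the RBF-SVM on a labelled feature matrix.

    ``labels`` is a 0/1 vector (1 = positive/OMP); both classes must be
    present.  ``class_weight='balanced'`` is an optional extension for
    imbalanced sets, off by default.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValueError(f"feature matrix must be 2-D, got shape {X.shape}")
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels disagree in length")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to train")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    classes = set(y.tolist())
    if classes != {0, 1}:
        raise ValueError(f"labels must contain both classes 0 and 1, got {sorted(classes)}")

    scaler_min = scaler_range = None
    if scale:
        scaler_min = X.min(axis=0)
        rng = X.max(axis=0) - scaler_min
        rng[rng == 0.0] = 1.0  # constant feature: pass through unchanged
        scaler_range = rng
        X = (X - scaler_min) / scaler_range

    svc = SVC(kernel="rbf", gamma=config.gamma, C=config.cost,
              class_weight=class_weight)
    svc.fit(X, y)
    return TrainedModel(
        svc=svc,
        svm_config=config,
        pse_config=pse_config,
        scaler_min=scaler_min,
        scaler_range=scaler_range,
    )


def predict_scores(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Real-valued decision scores; higher = more OMP-like."""
    X = model._transform(features)
    if X.shape[0] == 0:
        return np.empty(0)
    # classes_ is [0, 1], so decision_function is already oriented
    # toward the positive class.
    return np.asarray(model.svc.decision_function(X), dtype=float)


def predict_labels(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Binary labels: positive iff score > 0 (score 0 ties to negative)."""
    return (predict_scores(model, features) > 0).astype(int)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model with its full configuration for provenance."""
    payload = {
        "format": "pseomp-model",
        "version": __version__,
        "svm_config": model.svm_config,
        "pse_config": model.pse_config,
        "index_table_hash": (
            model.pse_config.index_table.content_hash()
            if model.pse_config is not None
            else None
        ),
        "svc": model.svc,
        "scaler_min": model.scaler_min,
        "scaler_range": model.scaler_range,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "pseomp-model":
        raise ValueError(f"{path} is not a pseomp model file")
    return TrainedModel(
        svc=payload["svc"],
        svm_config=payload["svm_config"],
        pse_config=payload["pse_config"],
        scaler_min=payload["scaler_min"],
        scaler_range=payload["scaler_range"],
    )
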