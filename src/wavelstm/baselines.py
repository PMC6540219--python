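"""KNN and SVM comparison classifiers (scikit-learn behind a thin wrapper).

The baselines consume exactly the same feature matrices and split plans as the
BiLSTM classifier, so any accuracy difference in a results table is
attributable to the classifier alone.  Defaults — k = 5 with Euclidean
distance, linear-kernel SVM with C = 1 — are deliberately plain and are
recorded alongside every result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = ["BaselineConfig", "FittedBaseline", "fit_baseline", "predict_baseline"]


@dataclass(frozen=True)
class BaselineConfig:
    method: Literal["knn", "svm"] = "knn"
    k: int = 5
    kernel: str = "linear"
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("knn", "svm"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.method == "knn" and (self.k < 1 or self.k % 2 == 0):
            raise ValueError("k must be odd and >= 1 (avoids two-class ties)")


@dataclass
class FittedBaseline:
    config: BaselineConfig
    estimator: object
    n_features: int


def fit_baseline(features: np.ndarray, labels: np.ndarray,
                 config: BaselineConfig) -> FittedBaseline:
    """Fit a KNN or SVM on a feature matrix (any width: 4096 raw or 2054 cA)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("baseline training requires at least two classes")
    if config.method == "knn":
        est = KNeighborsClassifier(n_neighbors=config.k, metric="euclidean")
    else:
        est = SVC(kernel=config.kernel, C=config.C, random_state=config.seed)
    est.fit(X, y)
    return FittedBaseline(config=config, estimator=est, n_features=X.shape[1])


def predict_baseline(model: FittedBaseline, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=np.float64)
    if X.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match fit width {model.n_features}"
        )
    return np.asarray(model.estimator.predict(X), dtype=np.int64)
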