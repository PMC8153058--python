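"""Shrinkage-regularized linear discriminant analysis.

Fits per-class means and a pooled within-class covariance shrunk toward its
scaled identity, ``(1 - lam) * S + lam * (tr(S) / d) * I``, which keeps the
covariance positive-definite even when trials are fewer than voxels.
Prediction is by maximum linear discriminant

    g_c(x) = x' Sigma^-1 mu_c - 0.5 * mu_c' Sigma^-1 mu_c + log prior_c

with exact ties broken toward the lowest class label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg


@dataclass
class ShrinkageLDA:
    shrinkage: float = 0.01
    priors: np.ndarray | None = None

    class_labels_: np.ndarray | None = None
    class_means_: np.ndarray | None = None
    pooled_cov_: np.ndarray | None = None
    # cached solve of Sigma^-1 @ means' for fast discriminants
    _coef: np.ndarray | None = None
    _intercept: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError("shrinkage must lie in [0, 1]")

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        labels, counts = np.unique(y, return_counts=True)
        if labels.size < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < 1:
            raise ValueError("every class needs at least one sample")
        if counts.min() != counts.max():
            raise ValueError(
                f"unbalanced classes (counts {dict(zip(labels.tolist(), counts.tolist()))}); "
                "training sets must be balanced"
            )
        n, d = X.shape
        c = labels.size
        means = np.stack([X[y == lab].mean(axis=0) for lab in labels])
        centered = X - means[np.searchsorted(labels, y)]
        # pooled within-class covariance; falls back to ddof 0 when every
        # class has a single sample (covariance is then all zeros anyway)
        denom = max(n - c, 1)
        S = centered.T @ centered / denom
        lam = self.shrinkage
        target = np.trace(S) / d
        sigma = (1.0 - lam) * S + lam * target * np.eye(d)
        if self.priors is None:
            priors = np.full(c, 1.0 / c)
        else:
            priors = np.asarray(self.priors, dtype=float)
            if priors.size != c or not np.isclose(priors.sum(), 1.0):
                raise ValueError("priors must match classes and sum to 1")
        try:
            cho = linalg.cho_factor(sigma)
            sol = linalg.cho_solve(cho, means.T)  # d x c
        except linalg.LinAlgError:
            sol = linalg.solve(sigma, means.T, assume_a="sym")
        self.class_labels_ = labels
        self.class_means_ = means
        self.pooled_cov_ = sigma
        self._coef = sol
        self._intercept = -0.5 * np.einsum("cd,dc->c", means, sol) \
            + np.log(priors)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Discriminant value per class (rows align with input trials)."""
        if self._coef is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self._coef.shape[0]:
            raise ValueError(
                f"test voxel count {X.shape[1]} does not match model "
                f"({self._coef.shape[0]})"
            )
        return X @ self._coef + self._intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        g = self.decision_function(X)
        # argmax returns the first (lowest-label) maximum, the tie-break rule
        return self.class_labels_[np.argmax(g, axis=1)]

    def to_json(self) -> str:
        if self.class_labels_ is None:
            raise RuntimeError("model is not fitted")
        return json.dumps({
            "shrinkage": self.shrinkage,
            "class_labels": self.class_labels_.tolist(),
            "class_means": self.class_means_.tolist(),
            "pooled_cov": self.pooled_cov_.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "ShrinkageLDA":
        blob = json.loads(text)
        model = cls(shrinkage=blob["shrinkage"])
        labels = np.asarray(blob["class_labels"])
        means = np.asarray(blob["class_means"], dtype=float)
        sigma = np.asarray(blob["pooled_cov"], dtype=float)
        sol = linalg.solve(sigma, means.T, assume_a="sym")
        model.class_labels_ = labels
        model.class_means_ = means
        model.pooled_cov_ = sigma
        model._coef = sol
        model._intercept = -0.5 * np.einsum("cd,dc->c", means, sol) \
            + np.log(np.full(labels.size, 1.0 / labels.size))
        return model
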