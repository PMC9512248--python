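"""Logistic-regression classification on the per-patch summary statistics.

Two evaluation protocols mirror the two ways the image-computable models
are scored:

* ``by_image_blocks``: images are split into 5 blocks; the classifier is
  trained on patches from 4 blocks and tested on patches from the held-out
  block, so the test images never overlap the training images.  Mean
  train/test accuracy over the 5 folds estimates generalization to novel
  images.
* ``uniform_resample``: training and test patches are sampled uniformly
  with replacement from the whole dataset (train_n / test_n patches),
  which scores generalization to similar patches and is typically more
  optimistic.

Features are z-scored on each training fold before fitting (disable with
``standardize=False``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = ["EvaluationProtocol", "fit_logistic", "evaluate"]


@dataclass(frozen=True)
class EvaluationProtocol:
    """How train/test splits are formed."""

    mode: str  # "by_image_blocks" | "uniform_resample"
    n_folds: int = 5
    train_n: int = 16000
    test_n: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("by_image_blocks", "uniform_resample"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")


@dataclass
class LogisticFit:
    weights: np.ndarray
    bias: float
    mean: Optional[np.ndarray] = None  # z-scoring parameters, if used
    scale: Optional[np.ndarray] = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.mean is not None:
            X = (X - self.mean) / self.scale
        return X @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision(X) >= 0).astype(int)

    def log_likelihood(self, X: np.ndarray, y: np.ndarray) -> float:
        """Unpenalized Bernoulli log-likelihood of labels y."""
        u = self.decision(X)
        y = np.asarray(y, dtype=float)
        return float(np.sum(y * u - np.logaddexp(0.0, u)))


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    l2_lambda: float = 1e-4,
    standardize: bool = True,
) -> LogisticFit:
    """Penalized maximum-likelihood logistic fit (deterministic, convex)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array")
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present")
    mean = scale = None
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - mean) / scale
    clf = LogisticRegression(
        C=1.0 / max(l2_lambda, 1e-12), solver="lbfgs", max_iter=1000, tol=1e-10
    )
    clf.fit(X, y)
    return LogisticFit(
        weights=clf.coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        mean=mean,
        scale=scale,
    )


def _fold_indices(
    protocol: EvaluationProtocol,
    n: int,
    image_ids: Optional[Sequence],
) -> Sequence[Tuple[np.ndarray, np.ndarray]]:
    rng = np.random.default_rng(protocol.seed)
    if protocol.mode == "by_image_blocks":
        if image_ids is None:
            raise ValueError("by_image_blocks requires image_ids")
        ids = np.asarray(image_ids)
        unique = np.array(sorted(set(ids.tolist())))
        order = rng.permutation(len(unique))
        blocks = np.array_split(unique[order], protocol.n_folds)
        folds = []
        for block in blocks:
            test = np.isin(ids, block)
            folds.append((np.flatnonzero(~test), np.flatnonzero(test)))
        return folds
    folds = []
    for _ in range(protocol.n_folds):
        tr = rng.integers(0, n, size=min(protocol.train_n, 4 * n))
        te = rng.integers(0, n, size=min(protocol.test_n, n))
        folds.append((tr, te))
    return folds


def evaluate(
    protocol: EvaluationProtocol,
    features: np.ndarray,
    labels: np.ndarray,
    image_ids: Optional[Sequence] = None,
    l2_lambda: float = 1e-4,
    fit_fn=None,
) -> pd.DataFrame:
    """Per-fold train/test accuracy under the given protocol.

    ``fit_fn(X_train, y_train)`` may replace the default logistic fit with
    any object exposing ``predict``; this lets the same protocol machinery
    score the front-end models.  Folds where either split lacks a class
    are flagged (``valid=False``) and excluded from summaries.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if fit_fn is None:
        fit_fn = lambda Xt, yt: fit_logistic(Xt, yt, l2_lambda)  # noqa: E731
    rows = []
    for fold, (tr, te) in enumerate(
        _fold_indices(protocol, len(y), image_ids)
    ):
        if protocol.mode == "by_image_blocks" and image_ids is not None:
            ids = np.asarray(image_ids)
            assert not set(ids[tr]) & set(ids[te])
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            warnings.warn(f"fold {fold}: a split lacks a class; excluded")
            rows.append(
                {"fold": fold, "train_acc": np.nan, "test_acc": np.nan,
                 "n_train": len(tr), "n_test": len(te), "valid": False}
            )
            continue
        fit = fit_fn(X[tr], y[tr])
        rows.append(
            {
                "fold": fold,
                "train_acc": float(np.mean(fit.predict(X[tr]) == y[tr])),
                "test_acc": float(np.mean(fit.predict(X[te]) == y[te])),
                "n_train": len(tr),
                "n_test": len(te),
                "valid": True,
            }
        )
    return pd.DataFrame(rows)
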