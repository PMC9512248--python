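"""GFB and FRF edge classifiers on the pooled filter-bank features.

The **GFB** (Gabor Filter Bank) classifier is binomial logistic regression
on the 1800 pooled front-end responses: 1800 weights + 1 bias = 1801
trainable parameters.  The **FRF** (Filter-Rectify-Filter) classifier
inserts a hidden layer of K relu units between the front-end and the
logistic readout, the standard second-order (texture) vision architecture:
1800*K hidden weights + K hidden biases + K readout weights + 1 bias.

Both are trained by minimizing L2-penalized cross-entropy (penalty on
weights, not biases).  The GFB fit is convex and deterministic; the FRF
fit is a seeded first-order (Adam) optimization with a fixed epoch budget.
Model output is an occlusion probability p, convertible to the log-odds
u = ln(p / (1 - p)); u > 0 means occlusion evidence dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .gabor_frontend import (
    GaborBankSpec,
    frontend_backward,
    frontend_forward_cache,
)

__all__ = [
    "EdgeClassifier",
    "ModelPrediction",
    "train",
    "predict",
    "log_odds",
    "inverse_log_odds",
    "parameter_count",
    "optimal_stimulus",
]


def log_odds(p: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """u = ln(p / (1 - p)).  Undefined (error) at p = 0 and p = 1."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("log-odds undefined at p = 0 or p = 1")
    u = np.log(p / (1.0 - p))
    return float(u) if u.ndim == 0 else u


def inverse_log_odds(u: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """Logistic sigmoid p = 1 / (1 + exp(-u))."""
    u = np.asarray(u, dtype=float)
    p = np.where(u >= 0, 1.0 / (1.0 + np.exp(-u)),
                 np.exp(u) / (1.0 + np.exp(u)))
    return float(p) if p.ndim == 0 else p


def parameter_count(kind: str, n_features: int = 1800, K: int = 0) -> int:
    """Trainable parameter count: GFB = d + 1; FRF = d*K + 2K + 1."""
    if kind == "gfb":
        return n_features + 1
    if kind == "frf":
        return n_features * K + 2 * K + 1
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclass(frozen=True)
class ModelPrediction:
    """Occlusion probability with its matching log-odds."""

    p: np.ndarray
    u: np.ndarray


@dataclass
class EdgeClassifier:
    """Trained GFB (linear readout) or FRF (K hidden relu units) model."""

    kind: str  # "gfb" | "frf"
    readout_weights: np.ndarray  # (d,) for GFB, (K,) for FRF
    readout_bias: float
    hidden_weights: Optional[np.ndarray] = None  # (K, d), FRF only
    hidden_biases: Optional[np.ndarray] = None  # (K,), FRF only
    K: int = 0
    l2_lambda: float = 0.0
    seed: Optional[int] = None
    loss_curve: Optional[np.ndarray] = None
    trained_on: Optional[str] = None

    @property
    def n_features(self) -> int:
        if self.kind == "gfb":
            return self.readout_weights.size
        return self.hidden_weights.shape[1]

    @property
    def n_parameters(self) -> int:
        return parameter_count(self.kind, self.n_features, self.K)

    def decision(self, features: np.ndarray) -> np.ndarray:
        """Log-odds u for a (n, d) feature matrix."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if self.kind == "gfb":
            return X @ self.readout_weights + self.readout_bias
        h = np.maximum(X @ self.hidden_weights.T + self.hidden_biases, 0.0)
        return h @ self.readout_weights + self.readout_bias


def train(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str = "gfb",
    K: int = 6,
    l2_lambda: float = 1.0,
    seed: int = 0,
    max_iter: int = 400,
) -> EdgeClassifier:
    """Fit a GFB or FRF classifier with L2 penalty ``l2_lambda``.

    Labels are binary with 1 = occlusion.  The objective is the
    cross-entropy plus an L2 penalty of strength ``l2_lambda`` on the
    weights (biases unpenalized), in the respective solver's convention.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size != 2 or not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes, coded 0/1")
    if kind == "gfb":
        # sklearn objective: sum CE + (1/(2C))||w||^2  ->  C = 1/l2_lambda
        clf = LogisticRegression(
            C=1.0 / max(l2_lambda, 1e-12),
            solver="lbfgs",
            max_iter=max_iter,
            tol=1e-8,
        )
        clf.fit(X, y)
        model = EdgeClassifier(
            kind="gfb",
            readout_weights=clf.coef_[0].copy(),
            readout_bias=float(clf.intercept_[0]),
            l2_lambda=l2_lambda,
            seed=seed,
        )
    elif kind == "frf":
        clf = MLPClassifier(
            hidden_layer_sizes=(K,),
            activation="relu",
            solver="adam",
            alpha=l2_lambda,
            max_iter=max_iter,
            random_state=seed,
            early_stopping=False,
            n_iter_no_change=max_iter,  # fixed epoch budget, no early stop
        )
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            clf.fit(X, y)
        model = EdgeClassifier(
            kind="frf",
            readout_weights=clf.coefs_[1][:, 0].copy(),
            readout_bias=float(clf.intercepts_[1][0]),
            hidden_weights=clf.coefs_[0].T.copy(),
            hidden_biases=clf.intercepts_[0].copy(),
            K=K,
            l2_lambda=l2_lambda,
            seed=seed,
            loss_curve=np.asarray(clf.loss_curve_),
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    u = model.decision(X)
    if not np.all(np.isfinite(u)):
        raise RuntimeError("training diverged: non-finite decision values")
    return model


def predict(
    model: EdgeClassifier,
    features: np.ndarray,
) -> ModelPrediction:
    """Occlusion probability and log-odds for features (n, d) or (d,)."""
    single = np.asarray(features).ndim == 1
    u = model.decision(features)
    p = inverse_log_odds(u)
    if single:
        return ModelPrediction(p=float(p[0]), u=float(u[0]))
    return ModelPrediction(p=p, u=u)


def predict_patches(
    model: EdgeClassifier,
    patches: np.ndarray,
    bank: Sequence,
    spec: GaborBankSpec = GaborBankSpec(),
) -> ModelPrediction:
    """Convenience: run the front-end then the classifier."""
    from .gabor_frontend import apply_frontend_batch

    patches = np.asarray(patches, dtype=float)
    if patches.ndim == 2:
        patches = patches[None]
    X = apply_frontend_batch(patches, bank, spec)
    return predict(model, X)


def _objective_and_grad(
    model: EdgeClassifier,
    pixels: np.ndarray,
    bank: Sequence,
    spec: GaborBankSpec,
    target: Union[str, Tuple[str, int]],
) -> Tuple[float, np.ndarray]:
    cache = frontend_forward_cache(pixels, bank, spec)
    v = cache["features"]
    if target == "output":
        u = model.decision(v[None])[0]
        if model.kind == "gfb":
            grad_v = model.readout_weights
        else:
            pre = model.hidden_weights @ v + model.hidden_biases
            mask = (pre > 0).astype(float)
            grad_v = (model.readout_weights * mask) @ model.hidden_weights
        return float(u), frontend_backward(grad_v, cache, bank, spec)
    kind, k = target
    if kind != "hidden_unit" or model.kind != "frf":
        raise ValueError("hidden-unit targets require an FRF model")
    pre = model.hidden_weights[k] @ v + model.hidden_biases[k]
    grad_v = model.hidden_weights[k] * (1.0 if pre > 0 else 0.0)
    return float(max(pre, 0.0)), frontend_backward(grad_v, cache, bank, spec)


def optimal_stimulus(
    model: EdgeClassifier,
    bank: Sequence,
    direction: str = "maximize",
    target: Union[str, Tuple[str, int]] = "output",
    seed: int = 0,
    n_restarts: int = 3,
    n_steps: int = 150,
    step_size: float = 0.05,
    spec: GaborBankSpec = GaborBankSpec(),
) -> Tuple[np.ndarray, float]:
    """Pixel-domain stimulus maximizing (or minimizing) a model signal.

    Projected gradient ascent/descent over pixel values constrained to
    [0, 1], with ``n_restarts`` seeded random initializations; returns the
    best stimulus and its objective value.  ``target`` is ``"output"``
    (the log-odds) or ``("hidden_unit", k)`` for an FRF hidden unit.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    sgn = 1.0 if direction == "maximize" else -1.0
    rng = np.random.default_rng(seed)
    size = spec.patch_size
    best_x: Optional[np.ndarray] = None
    best_val = -np.inf
    for _ in range(n_restarts):
        x = rng.uniform(0.3, 0.7, size=(size, size))
        for _ in range(n_steps):
            val, grad = _objective_and_grad(model, x, bank, spec, target)
            gnorm = np.linalg.norm(grad)
            if gnorm == 0:
                break
            x = np.clip(x + sgn * step_size * grad / gnorm, 0.0, 1.0)
        val, _ = _objective_and_grad(model, x, bank, spec, target)
        if sgn * val > best_val:
            best_val = sgn * val
            best_x = x
    return best_x, sgn * best_val
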