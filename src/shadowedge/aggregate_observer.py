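"""Aggregate-observer analysis: pooled human responses vs model outputs.

The aggregate observer (AO) over K participants classifying N images is
the vector of per-image proportions pi_i of observers responding
"occlusion".  A deterministic reading of the AO classifies image i as an
occlusion iff pi_i >= 0.5, yielding a 2x2 confusion matrix against the
true categories.  Whether the AO's errors are biased toward one category
is assessed with an exact two-sided binomial test on the error split
(null: both error types equally likely).  Agreement between the AO and a
model is measured with Spearman rank correlation of the per-image
probabilities — rank-based because some pi_i are exactly 0 or 1, where
the log-odds transform is undefined, and ranks are invariant to it.
Model comparisons use a bootstrap over images of the difference in
Spearman correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AggregateObserver",
    "ConfusionMatrix",
    "BiasTestResult",
    "build_ao",
    "ao_confusion",
    "bias_test",
    "model_human_correlation",
    "bootstrap_compare",
    "responses_from_table",
    "observer_inclusion",
]

OCCLUSION, SHADOW = 1, 0


@dataclass
class AggregateObserver:
    """Per-image occlusion-response proportions with true labels."""

    pi: np.ndarray
    labels: np.ndarray  # 1 = occlusion, 0 = shadow
    n_observers: int


@dataclass
class ConfusionMatrix:
    """counts[actual, predicted], rows/cols ordered (occlusion, shadow)."""

    counts: np.ndarray

    @property
    def errors(self) -> Tuple[int, int]:
        """(occlusions misclassified as shadows, shadows as occlusions)."""
        return int(self.counts[0, 1]), int(self.counts[1, 0])


@dataclass
class BiasTestResult:
    p: float
    n_errors: int
    e_occlusion: int  # occlusions called shadows
    e_shadow: int  # shadows called occlusions
    defined: bool = True


def build_ao(
    responses: np.ndarray, labels: Sequence[int]
) -> AggregateObserver:
    """AO proportions from an observers x images binary response matrix."""
    R = np.asarray(responses)
    if np.any(np.isnan(R.astype(float))):
        raise ValueError("missing responses are not allowed")
    if not np.isin(R, [0, 1]).all():
        raise ValueError("responses must be binary (1 = occlusion)")
    labels = np.asarray(labels, dtype=int)
    if labels.size != R.shape[1]:
        raise ValueError("one label per image is required")
    return AggregateObserver(
        pi=R.mean(axis=0), labels=labels, n_observers=R.shape[0]
    )


def ao_confusion(ao: AggregateObserver) -> ConfusionMatrix:
    """Deterministic rounding rule: predict occlusion iff pi >= 0.5."""
    predicted = (ao.pi >= 0.5).astype(int)
    counts = np.zeros((2, 2), dtype=int)
    for actual_cat, row in ((OCCLUSION, 0), (SHADOW, 1)):
        sel = ao.labels == actual_cat
        counts[row, 0] = int(np.sum(predicted[sel] == OCCLUSION))
        counts[row, 1] = int(np.sum(predicted[sel] == SHADOW))
    return ConfusionMatrix(counts=counts)


def bias_test(
    confusion: Union[ConfusionMatrix, Tuple[int, int]]
) -> BiasTestResult:
    """Exact two-sided binomial test on the split of the two error types.

    With e1 occlusions misclassified and e2 shadows misclassified,
    N = e1 + e2, the p-value is min(1, 2 * P(X <= min(e1, e2))) for
    X ~ Binomial(N, 1/2).  With N = 0 the test is undefined and p = 1 is
    returned with ``defined=False``.
    """
    if isinstance(confusion, ConfusionMatrix):
        e1, e2 = confusion.errors
    else:
        e1, e2 = int(confusion[0]), int(confusion[1])
    n = e1 + e2
    if n == 0:
        return BiasTestResult(
            p=1.0, n_errors=0, e_occlusion=e1, e_shadow=e2, defined=False
        )
    p = min(1.0, 2.0 * float(stats.binom.cdf(min(e1, e2), n, 0.5)))
    return BiasTestResult(p=p, n_errors=n, e_occlusion=e1, e_shadow=e2)


def model_human_correlation(
    ao: AggregateObserver, model_predictions: Sequence[float]
) -> float:
    """Spearman rank correlation between AO proportions and model p.

    Computed on probabilities: ranks are invariant to the monotone logit
    transform, so this equals the correlation of log-odds wherever the
    log-odds are defined, while tolerating pi = 0 or 1.  Mid-ranks are
    used for ties.
    """
    p = np.asarray(model_predictions, dtype=float)
    if p.size != ao.pi.size:
        raise ValueError("model predictions must cover the same image set")
    if np.ptp(p) == 0 or np.ptp(ao.pi) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(ao.pi, p).statistic)


def bootstrap_compare(
    ao: AggregateObserver,
    model_a_preds: Sequence[float],
    model_b_preds: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Bootstrap over images of delta_rho = rho_a - rho_b.

    Images are resampled with replacement ``n_boot`` times; the median
    and the 2.5/97.5 percentile bounds of the per-replicate difference in
    Spearman correlations are reported.
    """
    pa = np.asarray(model_a_preds, dtype=float)
    pb = np.asarray(model_b_preds, dtype=float)
    n = ao.pi.size
    if n < 20:
        raise ValueError("bootstrap_compare needs at least 20 images")
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rho_a = stats.spearmanr(ao.pi[idx], pa[idx]).statistic
        rho_b = stats.spearmanr(ao.pi[idx], pb[idx]).statistic
        deltas[b] = rho_a - rho_b
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    return {
        "median_delta_rho": float(np.median(deltas)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_boot": n_boot,
    }


def responses_from_table(table: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    """Observers x images matrix + labels from a per-trial long table.

    Expects columns observer_id, image_id, response (1 = occlusion),
    true_label (1 = occlusion / "occlusion").  Raises on missing cells.
    """
    labels_map = (
        table[["image_id", "true_label"]]
        .drop_duplicates()
        .set_index("image_id")["true_label"]
    )
    wide = table.pivot(
        index="observer_id", columns="image_id", values="response"
    )
    if wide.isna().any().any():
        raise ValueError("missing responses are not allowed")
    labels = labels_map.loc[wide.columns].to_numpy()
    if labels.dtype.kind in "OU":
        labels = (labels == "occlusion").astype(int)
    return wide.to_numpy().astype(int), labels.astype(int)


def observer_inclusion(
    n_correct: int, n_trials: int = 200, threshold: int = 114
) -> bool:
    """Screening filter: include an observer with >= threshold correct.

    The threshold is taken as a parameter of the screening procedure, not
    derived from a significance level.
    """
    if not 0 <= n_correct <= n_trials:
        raise ValueError("n_correct must be between 0 and n_trials")
    return n_correct >= threshold
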