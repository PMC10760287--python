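"""Evaluation statistics shared by every experiment harness.

Fidelity between a model's scores and the programmed risk score is measured
with the Spearman rank correlation and RMSE; discrimination between a case
set and a population test set with the Mann-Whitney AUC.  Uncertainty is
reported as 95% percentile-bootstrap intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MetricReport:
    """A point estimate with a percentile-bootstrap confidence interval."""

    metric: str
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    confidence: float = 0.95
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.metric not in {"spearman", "rmse", "auc", "pearson"}:
            raise ValueError(f"unknown metric {self.metric!r}")

    def width(self) -> float:
        return self.ci_high - self.ci_low


def spearman_rank(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of (tie-averaged) ranks."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have the same length")
    r = stats.spearmanr(a, b).statistic
    return float(r)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.std() == 0.0 or b.std() == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have the same length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def auc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties ½.

    Computed from tie-averaged ranks of the pooled scores, which is exactly
    the normalised U statistic.
    """
    pos = np.asarray(scores_pos, dtype=float).ravel()
    neg = np.asarray(scores_neg, dtype=float).ravel()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def bootstrap_ci(
    metric_fn: Callable[..., float],
    data: Sequence[np.ndarray],
    *,
    metric_name: str,
    n_boot: int = 1000,
    confidence: float = 0.95,
    seed: int = 0,
    stratified: bool = False,
) -> MetricReport:
    """Percentile bootstrap of ``metric_fn(*data)``.

    By default all arrays in ``data`` are resampled jointly (paired over
    samples; they must share their first dimension).  With ``stratified=True``
    each array is resampled independently with its own size preserved — used
    for AUC, where cases and non-cases are distinct groups.
    """
    arrays = [np.asarray(a) for a in data]
    rng = np.random.default_rng(seed)
    estimate = float(metric_fn(*arrays))
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    reps = np.empty(n_boot)
    if stratified:
        for i in range(n_boot):
            resampled = [a[rng.integers(0, a.shape[0], a.shape[0])] for a in arrays]
            reps[i] = metric_fn(*resampled)
    else:
        n = arrays[0].shape[0]
        if any(a.shape[0] != n for a in arrays):
            raise ValueError("paired bootstrap requires equal first dimensions")
        for i in range(n_boot):
            idx = rng.integers(0, n, n)
            reps[i] = metric_fn(*(a[idx] for a in arrays))

    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    # Percentile intervals from few resamples can exclude the point estimate;
    # clamp so the report invariant ci_low <= estimate <= ci_high holds.
    return MetricReport(
        metric=metric_name,
        estimate=estimate,
        ci_low=float(min(lo, estimate)),
        ci_high=float(max(hi, estimate)),
        n_boot=n_boot,
        confidence=confidence,
        seed=seed,
    )


def paired_bootstrap_indices(
    n: int, n_boot: int, seed: int
) -> np.ndarray:
    """Shared resample-index matrix so several methods see identical resamples."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(n_boot, n))
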