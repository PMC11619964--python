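"""Task heads over the latent embedding: classification, regression, survival.

Classification uses softmax cross-entropy (optionally inverse-frequency
class-weighted for imbalanced cohorts), regression uses mean squared
error. Survival uses multi-task logistic regression (MTLR): the time axis
is discretized into m intervals, each subject's outcome becomes a monotone
0/1 vector y switching from 0 to 1 in the interval of the event, and the
head scores y' in R^m define

    P(y | y') = exp(sum_i y_i y'_i) / sum_{j=0}^{m} exp(sum_{i=j+1}^{m} y'_i)

i.e. a softmax over the m+1 monotone configurations, parameterized by the
suffix sums of y'. Observed events contribute -log P of their
configuration; censored subjects contribute the marginal probability of
every configuration consistent with survival up to the censoring interval.
Survival curves and the discrete-hazard risk score r(x) = sum_i h(t_i, x)
follow from the configuration probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .synthetic_data import ConfigError


# ---------------------------------------------------------------------------
# classification / regression losses


def classification_loss(y_true: np.ndarray, y_logits: np.ndarray,
                        class_weights: np.ndarray | None = None,
                        return_grad: bool = False):
    """Mean softmax cross-entropy; optional per-class weights.

    With weights w, the loss is sum_i w[y_i] CE_i / sum_i w[y_i].
    """
    y = np.asarray(y_true, dtype=int)
    logits = np.atleast_2d(np.asarray(y_logits, dtype=float))
    n, n_classes = logits.shape
    if y.shape != (n,):
        raise ValueError("label/logit batch mismatch")
    if np.any((y < 0) | (y >= n_classes)):
        raise ValueError("label outside the declared class set")
    shifted = logits - logits.max(axis=1, keepdims=True)
    logZ = np.log(np.exp(shifted).sum(axis=1))
    logp = shifted - logZ[:, None]
    w = np.ones(n) if class_weights is None else np.asarray(class_weights, dtype=float)[y]
    wsum = w.sum()
    loss = float(-(w * logp[np.arange(n), y]).sum() / wsum)
    if not return_grad:
        return loss
    grad = np.exp(logp)
    grad[np.arange(n), y] -= 1.0
    grad *= (w / wsum)[:, None]
    return loss, grad


def regression_loss(y_true: np.ndarray, y_pred: np.ndarray,
                    return_grad: bool = False):
    """Mean squared error over the batch."""
    y = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != p.shape:
        raise ValueError("prediction/target length mismatch")
    err = p - y
    loss = float(np.mean(err ** 2))
    if not return_grad:
        return loss
    return loss, (2.0 * err / err.size)


def inverse_frequency_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(np.asarray(y, dtype=int), minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    w = 1.0 / counts
    return w * n_classes / w.sum()


# ---------------------------------------------------------------------------
# time discretization and survival labels


@dataclass
class TimeGrid:
    """Interval boundaries t_0 = 0 < t_1 < ... < t_m covering the data."""

    boundaries: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("grid needs at least one interval")
        if b[0] != 0.0:
            raise ValueError("t_0 must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        self.boundaries = b

    @property
    def m(self) -> int:
        return self.boundaries.size - 1

    def interval_of(self, t: float) -> int:
        """1-based index of the interval [t_{i-1}, t_i) containing t.

        Times at or beyond t_m are assigned to the last interval with a
        warning.
        """
        if t < 0:
            raise ValueError("negative time")
        if t >= self.boundaries[-1]:
            warnings.warn(f"time {t} beyond the grid's last boundary; "
                          "assigned to the last interval")
            return self.m
        return int(np.searchsorted(self.boundaries, t, side="right"))


def make_time_grid(times: np.ndarray, m_intervals: int = 10,
                   strategy: str = "quantile",
                   events: np.ndarray | None = None) -> TimeGrid:
    """Discretize the time axis into m intervals.

    ``quantile`` (default) places interior boundaries at empirical
    quantiles of observed event times (all times when no event indicator
    is given); ``uniform`` uses equal widths. The last boundary sits just
    above the maximum observed time so every observation falls inside the
    grid. Duplicate quantile boundaries are collapsed, shrinking m with a
    warning.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("no times given")
    if np.any(t < 0):
        raise ValueError("negative times")
    if m_intervals < 1:
        raise ConfigError(f"m_intervals must be >= 1, got {m_intervals}")
    t_max = float(t.max()) * (1.0 + 1e-9) + 1e-12
    if strategy == "uniform":
        bounds = np.linspace(0.0, t_max, m_intervals + 1)
    elif strategy == "quantile":
        ref = t if events is None else (t[np.asarray(events).astype(bool)]
                                        if np.any(events) else t)
        qs = np.quantile(ref, np.linspace(0, 1, m_intervals + 1)[1:-1])
        interior = [q for q in qs if 0.0 < q < t_max]
        bounds = np.concatenate([[0.0], interior, [t_max]])
    else:
        raise ConfigError(f"unknown grid strategy {strategy!r}")
    unique = np.unique(bounds)
    if unique.size < bounds.size:
        warnings.warn(f"tied boundaries collapsed: m reduced from "
                      f"{bounds.size - 1} to {unique.size - 1}")
    return TimeGrid(unique)


@dataclass
class SurvivalLabel:
    """Discrete-time outcome: event indicator and 1-based interval index.

    For an observed event (E=1) the label vector y has its single 0->1
    switch at the event's interval: y_i = 1 iff i >= interval. For a
    censored subject (E=0) ``interval`` records the censoring interval;
    every monotone configuration with switch index >= interval (including
    the all-zero vector) is consistent with the observation.
    """

    event: int
    interval: int
    m: int

    def __post_init__(self) -> None:
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if not 1 <= self.interval <= self.m:
            raise ValueError("interval index out of range")

    @property
    def y(self) -> np.ndarray:
        vec = np.zeros(self.m, dtype=int)
        vec[self.interval - 1:] = 1
        return vec

    def compatible_switches(self) -> np.ndarray:
        """Switch indices (1..m+1; m+1 = no event within the grid) of the
        monotone configurations consistent with this observation."""
        if self.event == 1:
            return np.array([self.interval])
        return np.arange(self.interval, self.m + 2)


def encode_survival_label(T: float, E: int, grid: TimeGrid) -> SurvivalLabel:
    """Map an observed (time, event) pair onto the discrete grid."""
    if E not in (0, 1):
        raise ValueError("event indicator must be 0 or 1")
    return SurvivalLabel(event=int(E), interval=grid.interval_of(float(T)), m=grid.m)


# ---------------------------------------------------------------------------
# MTLR likelihood


def _switch_from_y(y: np.ndarray) -> int:
    y = np.asarray(y, dtype=int)
    if np.any(np.diff(y) < 0) or not np.all(np.isin(y, [0, 1])):
        raise ValueError("survival label must be a monotone 0/1 vector")
    ones = np.flatnonzero(y)
    return int(ones[0]) + 1 if ones.size else y.size + 1


def _suffix_logits(y_scores: np.ndarray) -> np.ndarray:
    """A_s = sum_{i=s}^{m} y'_i for s = 1..m+1 (A_{m+1} = 0)."""
    s = np.asarray(y_scores, dtype=float)
    return np.concatenate([np.cumsum(s[::-1])[::-1], [0.0]])


def mtlr_log_probability(y: np.ndarray, y_scores: np.ndarray) -> float:
    """log P(y | y') of one monotone configuration (log-sum-exp guarded)."""
    A = _suffix_logits(y_scores)
    s = _switch_from_y(y)
    return float(A[s - 1] - logsumexp(A))


def mtlr_configuration_probabilities(y_scores: np.ndarray) -> np.ndarray:
    """P over the m+1 monotone configurations, indexed by switch 1..m+1."""
    A = _suffix_logits(y_scores)
    return np.exp(A - logsumexp(A))


def survival_loss(labels: Sequence[SurvivalLabel], y_scores_batch: np.ndarray,
                  return_grad: bool = False):
    """Mean negative MTLR log-likelihood over a batch.

    Uncensored subjects contribute -log P(y); censored subjects the
    marginal -log sum over configurations consistent with survival to the
    censoring interval.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty batch")
    scores = np.atleast_2d(np.asarray(y_scores_batch, dtype=float))
    n, m = scores.shape
    if len(labels) != n:
        raise ValueError("label/score batch mismatch")
    loss = 0.0
    grad = np.zeros_like(scores) if return_grad else None
    for i, (lab, row) in enumerate(zip(labels, scores)):
        if lab.m != m:
            raise ValueError("label grid size does not match score width")
        A = _suffix_logits(row)
        logZ = logsumexp(A)
        comp = lab.compatible_switches() - 1  # 0-based into A
        lognum = logsumexp(A[comp])
        loss += (logZ - lognum) / n
        if return_grad:
            p_all = np.exp(A - logZ)
            p_comp = np.zeros_like(A)
            p_comp[comp] = np.exp(A[comp] - lognum)
            # y'_i appears in A_s iff s <= i (1-based), so d/dy'_i sums p over s<=i
            grad[i] = (np.cumsum(p_all[:-1]) - np.cumsum(p_comp[:-1])) / n
    if return_grad:
        return float(loss), grad
    return float(loss)


# ---------------------------------------------------------------------------
# survival curves and risk


def predict_survival_curve(y_scores: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """S(t_i) for i = 1..m: probability mass of configurations with the
    event after t_i (switch index > i)."""
    p = mtlr_configuration_probabilities(y_scores)
    if p.size != grid.m + 1:
        raise ValueError("score width does not match the grid")
    # S(t_i) = sum_{s > i} p_s
    return np.cumsum(p[::-1])[::-1][1:]


def risk_score(y_scores: np.ndarray, grid: TimeGrid) -> float:
    """Sum of discrete hazards r = sum_i h_i, h_i = (S_{i-1} - S_i)/S_{i-1}.

    S_0 = 1; an exhausted survival mass (S_{i-1} = 0) pins h_i = 1. Higher
    risk means an earlier expected event; the score is invariant to adding
    a constant to all interval scores.
    """
    S = predict_survival_curve(y_scores, grid)
    S_prev = np.concatenate([[1.0], S[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(S_prev > 0, (S_prev - S) / S_prev, 1.0)
    return float(h.sum())


@dataclass
class TaskHeadSpec:
    """Shape of one downstream head attached to the latent embedding."""

    kind: str                      # classification | regression | survival
    output_width: int              # n classes | 1 | m intervals
    hidden_dims: tuple[int, ...] = (64,)

    def __post_init__(self) -> None:
        if self.kind not in ("classification", "regression", "survival"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.kind == "regression" and self.output_width != 1:
            raise ValueError("regression head has a single output neuron")
        if self.output_width < 1:
            raise ValueError("output width must be >= 1")
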