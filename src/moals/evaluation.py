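"""Stratified cross-validation harness and the reported metrics.

Classification: accuracy, precision, recall, F1 and ROC-AUC (positive
class = case). Regression: RMSE, MAE, MedAE, R^2. Survival: Harrell's
concordance index over censoring-comparable pairs, and the integrated
Brier score with inverse-probability-of-censoring weights (IPCW) from a
Kaplan-Meier estimate of the censoring distribution. Fold-level metrics
carry t-distribution 95% confidence intervals, plus Cohen's d between the
predicted case probabilities of the two groups.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold

from .downstream_tasks import TimeGrid
from .io_formats import OmicsBlock, SampleTable
from .multitask_training import MoalsNetwork


# ---------------------------------------------------------------------------
# fold assignment


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Seeded stratified fold assignment: per-sample fold index in 0..k-1.

    Every class must have at least k members; within each fold the class
    proportions match the global ones to within one sample per class.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < k]
    if too_small.size:
        raise ValueError(f"class {too_small[0]!r} has fewer than {k} members")
    folds = np.empty(y.size, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        folds[test_idx] = fold
    return folds


# ---------------------------------------------------------------------------
# metric families


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                           y_prob: np.ndarray | None = None,
                           pos_label: int = 1) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and (given scores) ROC-AUC."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = {
        "accuracy": float(skm.accuracy_score(y_true, y_pred)),
        "precision": float(skm.precision_score(y_true, y_pred, pos_label=pos_label,
                                               zero_division=0)),
        "recall": float(skm.recall_score(y_true, y_pred, pos_label=pos_label,
                                         zero_division=0)),
        "f1": float(skm.f1_score(y_true, y_pred, pos_label=pos_label,
                                 zero_division=0)),
    }
    if y_prob is not None:
        if np.unique(y_true).size < 2:
            raise ValueError("AUC undefined for single-class y_true")
        out["auc"] = float(skm.roc_auc_score(y_true, y_prob))
    return out


def regression_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                       include_r2: bool = True) -> dict[str, float]:
    """RMSE, MAE, MedAE and (unless disabled) R^2.

    R^2 is undefined for a constant target; pass ``include_r2=False`` to
    get the error metrics alone in that case.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    out = {
        "rmse": float(np.sqrt(skm.mean_squared_error(y, p))),
        "mae": float(skm.mean_absolute_error(y, p)),
        "medae": float(skm.median_absolute_error(y, p)),
    }
    if include_r2:
        if np.all(y == y[0]):
            raise ValueError("R^2 undefined for constant y_true")
        out["r2"] = float(skm.r2_score(y, p))
    return out


def concordance_index(T: np.ndarray, E: np.ndarray, risk: np.ndarray) -> float:
    """Harrell's C over censoring-comparable pairs.

    A pair is comparable when the earlier time carries an observed event;
    it is concordant when that sample has the higher predicted risk. Risk
    ties count 0.5.
    """
    T = np.asarray(T, dtype=float)
    E = np.asarray(E, dtype=int)
    r = np.asarray(risk, dtype=float)
    concordant = 0.0
    n_pairs = 0
    n = T.size
    for i in range(n):
        if E[i] != 1:
            continue
        later = T > T[i]
        n_pairs += int(later.sum())
        concordant += float((r[i] > r[later]).sum()) + 0.5 * float((r[i] == r[later]).sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    return concordant / n_pairs


def _km_censoring_survival(T: np.ndarray, E: np.ndarray):
    """Kaplan-Meier estimate G(t) = P(C > t) of the censoring distribution.

    Returns a step-function evaluator; censoring (E=0) plays the role of
    the event.
    """
    T = np.asarray(T, dtype=float)
    cens = np.asarray(E, dtype=int) == 0
    order = np.argsort(T)
    times, surv = [], []
    at_risk = T.size
    G = 1.0
    i = 0
    Ts, Cs = T[order], cens[order]
    while i < Ts.size:
        t = Ts[i]
        d = 0
        nrisk = at_risk
        while i < Ts.size and Ts[i] == t:
            d += int(Cs[i])
            at_risk -= 1
            i += 1
        if d:
            G *= 1.0 - d / nrisk
            times.append(t)
            surv.append(G)
    times = np.asarray(times)
    surv = np.asarray(surv)

    def evaluate(t: np.ndarray, before: bool = False) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        side = "left" if before else "right"
        idx = np.searchsorted(times, t, side=side)
        out = np.ones(t.shape)
        mask = idx > 0
        out[mask] = surv[idx[mask] - 1]
        return out

    return evaluate


def integrated_brier_score(S_curves: np.ndarray, grid: TimeGrid,
                           T: np.ndarray, E: np.ndarray) -> float:
    """IPCW Brier score at each grid time, trapezoid-integrated and
    normalized by the time span.

    ``S_curves`` is samples x m of predicted S(t_i). If the censoring
    Kaplan-Meier reaches 0 before some grid time, the integration is
    truncated there with a warning.
    """
    S = np.atleast_2d(np.asarray(S_curves, dtype=float))
    T = np.asarray(T, dtype=float)
    E = np.asarray(E, dtype=int)
    times = grid.boundaries[1:]
    if S.shape != (T.size, times.size):
        raise ValueError("curve matrix does not match samples x grid")
    G = _km_censoring_survival(T, E)
    G_at_T = G(T, before=True)
    scores = []
    used_times = []
    for j, t in enumerate(times):
        G_t = float(G(np.array([t]))[0])
        died = (T <= t) & (E == 1)
        alive = T > t
        if np.any(died & (G_at_T <= 0)) or (np.any(alive) and G_t <= 0):
            warnings.warn(f"censoring survival reached 0 before t={t}; "
                          "integration truncated")
            break
        contrib = np.zeros(T.size)
        contrib[died] = (S[died, j] ** 2) / G_at_T[died]
        contrib[alive] = ((1.0 - S[alive, j]) ** 2) / G_t
        scores.append(float(contrib.mean()))
        used_times.append(float(t))
    if not scores:
        raise ValueError("no usable grid times for the Brier score")
    if len(scores) == 1:
        return scores[0]
    used_times = np.asarray(used_times)
    return float(np.trapezoid(scores, used_times) / (used_times[-1] - used_times[0]))


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled-SD denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def fold_confidence_interval(values: Sequence[float], level: float = 0.95
                             ) -> tuple[float, float]:
    """t-distribution CI of the mean across fold metrics."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return (float(v[0]), float(v[0])) if v.size else (np.nan, np.nan)
    half = stats.t.ppf(0.5 + level / 2, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return float(v.mean() - half), float(v.mean() + half)


# ---------------------------------------------------------------------------
# cross-validation harness


def cross_validate(blocks: Sequence[OmicsBlock], samples: SampleTable,
                   k: int = 5, seed: int = 0,
                   model_kwargs: dict | None = None) -> dict:
    """Stratified k-fold evaluation of the multi-task model.

    Each fold trains a fresh model on the other folds (scalers and the
    time grid are learned on training samples only, inside ``fit``) and
    scores the held-out fold on all three tasks. Returns per-fold and
    pooled (mean, 95% CI) metrics plus Cohen's d on the predicted case
    probabilities.
    """
    model_kwargs = dict(model_kwargs or {})
    folds = stratified_kfold(samples.label, k=k, seed=seed)
    per_fold: list[dict[str, float]] = []
    for fold in range(k):
        train_ids = [s for s, f in zip(samples.samples, folds) if f != fold]
        test_ids = [s for s, f in zip(samples.samples, folds) if f == fold]
        train_blocks = [b.subset_samples(train_ids) for b in blocks]
        test_blocks = [b.subset_samples(test_ids) for b in blocks]
        train_tab = samples.subset_samples(train_ids)
        test_tab = samples.subset_samples(test_ids)

        model = MoalsNetwork(random_state=seed + fold, **model_kwargs)
        model.fit(train_blocks, train_tab)

        prob = model.predict_proba(test_blocks)[:, 1]
        pred = model.predict(test_blocks)
        row = classification_metrics(test_tab.label, pred, prob)

        onset_mask = np.isfinite(test_tab.onset_age)
        if onset_mask.sum() >= 2 and np.unique(test_tab.onset_age[onset_mask]).size > 1:
            onset_pred = model.predict_onset(test_blocks)
            row.update(regression_metrics(test_tab.onset_age[onset_mask],
                                          onset_pred[onset_mask]))

        risk = model.predict_risk(test_blocks)
        row["c_index"] = concordance_index(test_tab.time, test_tab.event, risk)
        curves = model.predict_survival_curves(test_blocks)
        row["ibs"] = integrated_brier_score(curves, model.grid_,
                                            test_tab.time, test_tab.event)
        row["cohens_d"] = cohens_d(prob[test_tab.label == 1],
                                   prob[test_tab.label == 0])
        per_fold.append(row)

    keys = sorted(set().union(*per_fold))
    pooled = {}
    for key in keys:
        vals = [f[key] for f in per_fold if key in f]
        lo, hi = fold_confidence_interval(vals)
        pooled[key] = {"mean": float(np.mean(vals)), "ci_low": lo, "ci_high": hi}
    return {"folds": per_fold, "pooled": pooled,
            "fold_table": pd.DataFrame(per_fold)}
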