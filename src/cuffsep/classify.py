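"""From-scratch LDA with stratified balanced five-fold cross-validation.

Implements the decoding stack used for all cuff/site comparisons: a pooled-
covariance linear discriminant with optional shrinkage, seeded stratified
fold assignment (shared between paired cuffs), balanced (macro-recall)
scoring, fold-paired cuff differences, exhaustive electrode-pair search and
confusion-matrix differencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .features import FeatureTable

__all__ = [
    "LDAModel",
    "FoldAssignment",
    "ConfusionMatrix",
    "CVResult",
    "fit_lda",
    "predict_lda",
    "balanced_accuracy",
    "stratified_folds",
    "cross_validate",
    "fold_difference",
    "pair_search",
    "confusion_difference",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    class_means: np.ndarray      # classes x channels
    pooled_cov: np.ndarray       # channels x channels (after shrinkage)
    priors: np.ndarray           # per-class, sums to 1
    shrinkage: float
    class_ids: np.ndarray        # ordered ascending

    @property
    def n_classes(self) -> int:
        return len(self.class_ids)

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]


@dataclass
class FoldAssignment:
    fold_of_trial: np.ndarray    # per-trial fold index in {0..k-1}
    n_folds: int
    seed: int

    def __post_init__(self):
        self.fold_of_trial = np.asarray(self.fold_of_trial, dtype=int)
        if self.fold_of_trial.size and (
            self.fold_of_trial.min() < 0
            or self.fold_of_trial.max() >= self.n_folds
        ):
            raise ValueError("fold indices out of range")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray           # true x predicted
    class_ids: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.class_ids = np.asarray(self.class_ids)
        if self.counts.shape != (len(self.class_ids),) * 2:
            raise ValueError("counts must be square over class_ids")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")

    def row_normalised(self) -> np.ndarray:
        """Per-true-class proportions (rows sum to 1)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        if np.any(sums == 0):
            raise ValueError("every class needs at least one true trial")
        return self.counts / sums


@dataclass
class CVResult:
    fold_scores: np.ndarray      # balanced accuracy per fold, percent
    median_score: float
    confusion: ConfusionMatrix   # pooled over held-out folds
    folds: FoldAssignment

    def __post_init__(self):
        self.fold_scores = np.asarray(self.fold_scores, dtype=float)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

def fit_lda(table: FeatureTable, shrinkage: float = 0.05) -> LDAModel:
    """Pooled-covariance LDA with uniform priors.

    The within-class covariance S (denominator n - K) is shrunk as
    ``(1 - lam) * S + lam * mean(diag(S)) * I``; the default lam = 0.05
    keeps the estimate well conditioned at the trial counts used here.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    X, y = table.values, table.labels
    class_ids = np.unique(y)
    k = len(class_ids)
    n, p = X.shape
    if k < 2:
        raise ValueError("need at least 2 classes")
    if n < p:
        warnings.warn(
            f"fewer trials ({n}) than features ({p}); consider raising "
            "shrinkage", stacklevel=2,
        )
    means = np.empty((k, p))
    scatter = np.zeros((p, p))
    for j, cid in enumerate(class_ids):
        Xc = X[y == cid]
        if len(Xc) < 2:
            raise ValueError(f"class {cid} has fewer than 2 trials")
        means[j] = Xc.mean(axis=0)
        d = Xc - means[j]
        scatter += d.T @ d
    S = scatter / (n - k)
    cov = (1.0 - shrinkage) * S + shrinkage * np.mean(np.diag(S)) * np.eye(p)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            "shrunk pooled covariance is singular; raise the shrinkage "
            "parameter"
        ) from None
    return LDAModel(
        class_means=means,
        pooled_cov=cov,
        priors=np.full(k, 1.0 / k),
        shrinkage=shrinkage,
        class_ids=class_ids,
    )


def predict_lda(model: LDAModel, features: np.ndarray) -> np.ndarray:
    """Class with the highest linear discriminant score per row.

    delta_c(x) = x' Sigma^-1 mu_c - mu_c' Sigma^-1 mu_c / 2 + log pi_c;
    exact ties resolve to the lowest class_id.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.n_features})"
        )
    # Sigma^-1 mu_c via a single solve; Sigma is SPD by construction
    coef = np.linalg.solve(model.pooled_cov, model.class_means.T)  # p x k
    intercept = (
        -0.5 * np.sum(model.class_means * coef.T, axis=1) + np.log(model.priors)
    )
    scores = X @ coef + intercept
    # argmax returns the first maximum; class_ids are sorted ascending,
    # which implements the lowest-class_id tie rule
    return model.class_ids[np.argmax(scores, axis=1)]


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Macro-averaged per-class recall, in percent."""
    totals = cm.counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("every class needs at least one true trial")
    recalls = np.diag(cm.counts) / totals
    return 100.0 * float(np.mean(recalls))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def stratified_folds(
    labels: Sequence[int] | np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Seeded stratified fold assignment.

    Within each class, trials are shuffled then dealt round-robin to the k
    folds, so per-class fold counts differ by at most one.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.full(len(labels), -1, dtype=int)
    for cid in np.unique(labels):
        idx = np.flatnonzero(labels == cid)
        if len(idx) < k:
            raise ValueError(
                f"class {cid} has {len(idx)} trials, fewer than k={k}"
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    return FoldAssignment(fold_of_trial=folds, n_folds=k, seed=seed)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               class_ids: np.ndarray) -> np.ndarray:
    index = {cid: j for j, cid in enumerate(class_ids)}
    counts = np.zeros((len(class_ids),) * 2, dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[int(t)], index[int(p)]] += 1
    return counts


def cross_validate(
    table: FeatureTable,
    folds: FoldAssignment,
    shrinkage: float = 0.05,
) -> CVResult:
    """K-fold CV: per-fold balanced accuracy, median score, pooled confusion."""
    if len(folds.fold_of_trial) != table.n_trials:
        raise ValueError("fold assignment does not match the table")
    class_ids = np.unique(table.labels)
    pooled = np.zeros((len(class_ids),) * 2, dtype=int)
    scores = []
    for f in range(folds.n_folds):
        test = folds.fold_of_trial == f
        train = ~test
        sub = FeatureTable(
            values=table.values[train],
            labels=table.labels[train],
            trial_ids=table.trial_ids[train],
            channel_ids=table.channel_ids,
            normalised=table.normalised,
        )
        model = fit_lda(sub, shrinkage=shrinkage)
        pred = predict_lda(model, table.values[test])
        cm = _confusion(table.labels[test], pred, class_ids)
        scores.append(balanced_accuracy(ConfusionMatrix(cm, class_ids)))
        pooled += cm
    scores = np.asarray(scores)
    return CVResult(
        fold_scores=scores,
        median_score=float(np.median(scores)),
        confusion=ConfusionMatrix(pooled, class_ids),
        folds=folds,
    )


def fold_difference(result_a: CVResult, result_b: CVResult
                    ) -> tuple[np.ndarray, float]:
    """Per-fold score differences a - b, plus their median.

    Both results must share the same fold assignment over the same trials:
    the two cuffs record the same session simultaneously, so the comparison
    is paired by fold.
    """
    fa, fb = result_a.folds, result_b.folds
    if (
        fa.n_folds != fb.n_folds
        or len(fa.fold_of_trial) != len(fb.fold_of_trial)
        or np.any(fa.fold_of_trial != fb.fold_of_trial)
    ):
        raise ValueError(
            "fold_difference requires both results to share one fold "
            "assignment over the same trials"
        )
    diff = result_a.fold_scores - result_b.fold_scores
    return diff, float(np.median(diff))


def pair_search(
    table: FeatureTable,
    folds: FoldAssignment,
    shrinkage: float = 0.05,
) -> list[tuple[tuple[int, int], float]]:
    """Evaluate every unordered channel pair; rank by mean fold accuracy.

    All C(c, 2) pairs are scored with the same fold assignment; ties break
    toward lexicographically smaller channel index pairs.  Mean (not
    median) fold accuracy is used for ranking to reduce ties among the
    candidates.
    """
    c = table.n_channels
    if c < 2:
        raise ValueError("pair search needs at least 2 channels")
    results = []
    for i, j in combinations(range(c), 2):
        sub = table.select_channels([i, j])
        res = cross_validate(sub, folds, shrinkage=shrinkage)
        results.append(
            (
                (int(table.channel_ids[i]), int(table.channel_ids[j])),
                float(np.mean(res.fold_scores)),
            )
        )
    results.sort(key=lambda r: (-r[1], r[0]))
    return results


def confusion_difference(
    cm_a: ConfusionMatrix,
    cm_b: ConfusionMatrix,
    *,
    row_normalise: bool = True,
) -> np.ndarray:
    """Entrywise difference a - b of two confusion matrices.

    Row-normalised by default (per-class proportions, so rows of the
    difference sum to zero); with ``row_normalise=False`` raw counts are
    differenced.
    """
    if cm_a.counts.shape != cm_b.counts.shape or np.any(
        cm_a.class_ids != cm_b.class_ids
    ):
        raise ValueError("confusion matrices must share the same class set")
    if row_normalise:
        return cm_a.row_normalised() - cm_b.row_normalised()
    return cm_a.counts.astype(float) - cm_b.counts.astype(float)
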