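"""Fitting the linear feature-summation value model.

The model states that the subjective value of stimulus i is a weighted sum
of its feature values, v_i = sum_j w_j f_ij (with f_i0 = 1 the intercept),
the weights reflecting a participant's taste and shared across stimuli.
Ratings are treated as continuous and fit with ridge regression under
k-fold cross-validation; predictive accuracy is the Pearson correlation
between the pooled out-of-fold predictions and the observed ratings, and
its significance comes from a permutation null over stimulus labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

DEFAULT_PENALTIES = np.logspace(-4, 3, 15)


@dataclass
class CvPrediction:
    """Pooled out-of-fold predictions and their accuracy."""

    predictions: np.ndarray  # one prediction per stimulus
    fold_assignment: np.ndarray
    accuracy: float  # Pearson r(pooled predictions, ratings)
    degenerate: bool = False  # constant ratings: accuracy undefined


@dataclass
class WeightVector:
    weights: dict[str, float]
    intercept: float
    penalty: float = 0.0
    dropped: tuple[str, ...] = field(default_factory=tuple)

    def as_array(self, names) -> np.ndarray:
        return np.array([self.weights[n] for n in names])


def _zscore_train_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _fit_fold(Xtr, ytr, Xte, alpha):
    mu, sd = _zscore_train_stats(Xtr)
    model = Ridge(alpha=alpha)
    model.fit((Xtr - mu) / sd, ytr)
    return model.predict((Xte - mu) / sd)


def fit_ridge_cv(
    features,
    ratings,
    n_folds: int = 20,
    penalty_grid: np.ndarray = DEFAULT_PENALTIES,
    seed: int = 0,
    feature_names=None,
) -> tuple[WeightVector, CvPrediction]:
    """Cross-validated ridge fit of one participant's ratings.

    Features are z-scored with training-fold statistics only.  The penalty is
    chosen by nested cross-validation inside each training fold; pooled
    out-of-fold predictions cover every stimulus exactly once.  The returned
    weights are refit on all data at the most frequently selected penalty and
    are expressed on the z-scored feature scale.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(ratings, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and ratings must have matching rows")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    feature_names = list(feature_names)

    const = X.std(axis=0) == 0
    dropped = tuple(n for n, c in zip(feature_names, const) if c)
    if dropped:
        warnings.warn(f"dropping constant feature columns: {dropped}", stacklevel=2)
        X = X[:, ~const]
        feature_names = [n for n, c in zip(feature_names, const) if not c]

    n = X.shape[0]
    outer = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    preds = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    chosen = []
    for k, (tr, te) in enumerate(outer.split(X)):
        alpha = _select_penalty(X[tr], y[tr], penalty_grid, seed)
        chosen.append(alpha)
        preds[te] = _fit_fold(X[tr], y[tr], X[te], alpha)
        fold_of[te] = k

    if np.std(y) == 0 or np.std(preds) == 0:
        cv = CvPrediction(preds, fold_of, float("nan"), degenerate=True)
        alpha_final = float(np.median(chosen))
    else:
        acc = float(stats.pearsonr(preds, y)[0])
        cv = CvPrediction(preds, fold_of, acc)
        alpha_final = float(np.median(chosen))

    mu, sd = _zscore_train_stats(X)
    final = Ridge(alpha=alpha_final)
    final.fit((X - mu) / sd, y)
    wv = WeightVector(
        weights=dict(zip(feature_names, map(float, final.coef_))),
        intercept=float(final.intercept_),
        penalty=alpha_final,
        dropped=dropped,
    )
    return wv, cv


def _select_penalty(X, y, grid, seed, inner_folds: int = 5) -> float:
    """Inner-CV mean-squared-error selection over the penalty grid."""
    if len(grid) == 1:
        return float(grid[0])
    n = X.shape[0]
    inner = KFold(n_splits=min(inner_folds, n), shuffle=True, random_state=seed + 1)
    errs = np.zeros(len(grid))
    for tr, te in inner.split(X):
        mu, sd = _zscore_train_stats(X[tr])
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        for i, a in enumerate(grid):
            m = Ridge(alpha=a)
            m.fit(Xtr, y[tr])
            errs[i] += ((m.predict(Xte) - y[te]) ** 2).sum()
    return float(grid[int(np.argmin(errs))])


def permutation_test(
    features,
    ratings,
    observed_accuracy: float | None = None,
    n_perm: int = 10000,
    n_folds: int = 20,
    penalty_grid: np.ndarray = DEFAULT_PENALTIES,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Permutation null for the cross-validated predictive accuracy.

    Stimulus labels of the rating vector are permuted and the full
    cross-validation pipeline re-run for each permutation.  Returns
    ``(p, null)`` with p = (1 + #{null >= observed}) / (1 + n_perm); the
    chance level is the null mean.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    y = np.asarray(ratings, dtype=float)
    if observed_accuracy is None:
        _, cv = fit_ridge_cv(features, y, n_folds=n_folds,
                             penalty_grid=penalty_grid, seed=seed)
        observed_accuracy = cv.accuracy
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        _, cvp = fit_ridge_cv(features, yp, n_folds=n_folds,
                              penalty_grid=penalty_grid, seed=seed)
        null[b] = cvp.accuracy
    p = (1.0 + np.sum(null >= observed_accuracy)) / (1.0 + n_perm)
    return float(p), null
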