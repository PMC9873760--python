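"""Layerwise decoding of interpretable features from network activations.

Each feature is decoded from every ReLU layer's activations under
cross-validation: PCA (fit on training folds, retaining 80% of the training
variance) followed by ridge regression for continuous features or logistic
regression for categorical ones.  A feature's level is then read off the
slope of its decoding score across layers: significantly positive slope
(layer-label permutation test) means high-level, significantly negative
means low-level, otherwise unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression, RidgeCV
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

RIDGE_GRID = np.logspace(-3, 3, 13)


def layer_activations(net, images: np.ndarray) -> list[np.ndarray]:
    """Post-ReLU activation matrices (stimuli x units), one per layer."""
    _, acts = net.forward(images, record=True)
    return acts


def decode_feature_from_layer(
    acts: np.ndarray,
    feature: np.ndarray,
    kind: str = "continuous",
    n_folds: int = 10,
    variance_kept: float = 0.8,
    seed: int = 0,
) -> dict[str, float]:
    """Cross-validated decoding score of one feature from one layer.

    PCA is fit within each training fold only (components retaining
    ``variance_kept`` of the training variance), test activations projected
    with the training transform.  Continuous features: pooled-prediction
    Pearson r.  Categorical: accuracy, AUC and F1 of pooled predictions
    (folds stratified so no fold is single-class).
    """
    A = np.asarray(acts, dtype=float)
    y = np.asarray(feature, dtype=float)
    n = A.shape[0]
    if kind == "categorical":
        splitter = StratifiedKFold(min(n_folds, n), shuffle=True, random_state=seed)
        splits = splitter.split(A, y.astype(int))
    else:
        splitter = KFold(min(n_folds, n), shuffle=True, random_state=seed)
        splits = splitter.split(A)

    preds = np.empty(n)
    scores_cat = np.empty(n)
    for tr, te in splits:
        # centre only: per-unit variance scaling blows up on near-silent
        # units, and the PCA operates on raw activation covariance
        mu = A[tr].mean(axis=0)
        Ztr = A[tr] - mu
        Zte = A[te] - mu
        pca = PCA(n_components=min(len(tr) - 1, Ztr.shape[1]), random_state=seed)
        T = pca.fit_transform(Ztr)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_kept) + 1)
        T = T[:, :k]
        Tte = pca.transform(Zte)[:, :k]
        if kind == "continuous":
            model = RidgeCV(alphas=RIDGE_GRID)
            model.fit(T, y[tr])
            preds[te] = model.predict(Tte)
        else:
            model = LogisticRegression(max_iter=2000)
            model.fit(T, y[tr].astype(int))
            preds[te] = model.predict(Tte)
            scores_cat[te] = model.predict_proba(Tte)[:, 1]

    if kind == "continuous":
        if preds.std() == 0 or y.std() == 0:
            return {"score": 0.0, "r": 0.0}
        r = float(stats.pearsonr(preds, y)[0])
        return {"score": r, "r": r}
    yi = y.astype(int)
    acc = float((preds == yi).mean())
    auc = float(roc_auc_score(yi, scores_cat)) if len(np.unique(yi)) > 1 else 0.5
    f1 = float(f1_score(yi, preds.astype(int)))
    # AUC is the default slope metric: it varies smoothly with the decision
    # scores, where thresholded accuracy is step-like and noisier
    return {"score": auc, "accuracy": acc, "auc": auc, "f1": f1}


@dataclass
class SlopeClassification:
    slope: float
    p_value: float
    label: str  # "high" | "low" | "unclassified"
    scores: np.ndarray


def classify_feature_level(
    scores,
    n_perm: int = 10000,
    alpha: float = 0.001,
    seed: int = 0,
) -> SlopeClassification:
    """Classify a feature by the slope of decoding score across layers.

    The least-squares slope of score against layer index is compared with a
    null built by permuting layer labels.  The feature is high-level if the
    slope is significantly positive at ``alpha`` (one tail per sign),
    low-level if significantly negative, otherwise unclassified.  Constant
    scores are unclassified.
    """
    y = np.asarray(scores, dtype=float)
    L = y.size
    if L < 3:
        raise ValueError("need at least 3 layers of scores")
    x = np.arange(1, L + 1, dtype=float)
    if np.std(y) == 0:
        return SlopeClassification(0.0, 1.0, "unclassified", y)
    xc = x - x.mean()
    ssx = float(xc @ xc)
    slope = float(xc @ (y - y.mean()) / ssx)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, L)), axis=1)
    null = (y[perms] - y.mean()) @ xc / ssx
    if slope > 0:
        p = (1.0 + np.sum(null >= slope)) / (1.0 + n_perm)
        label = "high" if p < alpha else "unclassified"
    else:
        p = (1.0 + np.sum(null <= slope)) / (1.0 + n_perm)
        label = "low" if p < alpha else "unclassified"
    return SlopeClassification(slope, float(p), label, y)


def decoding_profile(
    net,
    images: np.ndarray,
    features: dict[str, tuple[np.ndarray, str]],
    n_folds: int = 10,
    n_perm: int = 10000,
    alpha: float = 0.001,
    seed: int = 0,
) -> dict[str, SlopeClassification]:
    """Full profile: decode each feature from every layer and classify it.

    ``features`` maps name -> (values, kind).
    """
    acts = layer_activations(net, images)
    out = {}
    for name, (vals, kind) in features.items():
        scores = np.array(
            [
                decode_feature_from_layer(a, vals, kind, n_folds=n_folds, seed=seed)[
                    "score"
                ]
                for a in acts
            ]
        )
        out[name] = classify_feature_level(scores, n_perm=n_perm, alpha=alpha,
                                           seed=seed)
    return out


def layer_pc_regressors(
    net, images: np.ndarray, n_pcs: int = 3, seed: int = 0
) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Top principal components of each layer, as encoding-model regressors.

    Returns (stimuli x (layers * n_pcs)) scores named ``layer{i}_pc{j}`` and
    the standard layer grouping {1-4, 5-9, 10-13, 14-15} truncated to the
    configured depth (the last group always covers the fully connected
    layers).
    """
    acts = layer_activations(net, images)
    cols = []
    names = []
    for i, a in enumerate(acts, start=1):
        k = min(n_pcs, a.shape[1], a.shape[0] - 1)
        pca = PCA(n_components=k, random_state=seed)
        s = pca.fit_transform(a - a.mean(axis=0))
        sd = s.std(axis=0)
        sd[sd == 0] = 1.0
        cols.append(s / sd)
        names.extend(f"layer{i}_pc{j + 1}" for j in range(k))
    X = np.column_stack(cols)
    L = len(acts)
    n_fc = len(net.config.fc_sizes)
    n_conv = L - n_fc
    bounds = [b for b in (4, 9, 13) if b < n_conv] + [n_conv]
    groups: dict[str, list[str]] = {}
    start = 1
    for b in bounds:
        groups[f"layers_{start}_{b}"] = [
            n for n in names if start <= int(n.split("_")[0][5:]) <= b
        ]
        start = b + 1
    groups[f"layers_{n_conv + 1}_{L}"] = [
        n for n in names if int(n.split("_")[0][5:]) > n_conv
    ]
    return X, {k: v for k, v in groups.items() if v}
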