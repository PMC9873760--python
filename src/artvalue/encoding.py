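"""Voxelwise encoding analyses and ROI hierarchy profiles.

Two routes quantify where low-level versus high-level features are encoded:

* the GLM route — parametric feature regressors at stimulus onset, a
  partial F test per feature group per voxel, thresholded at p < 0.001
  uncorrected;
* the cross-validated route — per-trial response amplitudes regressed on
  the features with a lasso penalty at each voxel, a sum-of-squared-weights
  statistic per group, and an empirical shuffled-label null pooled per ROI.

Both end in an ROI proportion profile: the fraction of significant voxels
per group in each ordered ROI, and a hierarchy index (rank correlation of
ROI order with the high-minus-low proportion difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .glm import DesignMatrix, GlmFit, build_design_matrix, fit_glm, group_f_test


@dataclass
class VoxelStatMap:
    """Per-voxel statistics and significance flags for named groups."""

    statistic: dict[str, np.ndarray]  # group -> (voxels,)
    significant: dict[str, np.ndarray]  # group -> bool (voxels,)
    alpha: float
    kind: str  # "f_test" | "sum_sq_weights"


def feature_glm(
    bold,
    design,
    modulators: pd.DataFrame,
    nuisance: pd.DataFrame | None = None,
    mode: str = "onset_stick",
) -> GlmFit:
    """Fit the feature-modulated GLM to every voxel."""
    dm = build_design_matrix(design, modulators=modulators, nuisance=nuisance,
                             mode=mode)
    return fit_glm(bold.data if hasattr(bold, "data") else bold, dm)


def group_f_maps(
    fit: GlmFit, groups: dict[str, list[str]], alpha: float = 0.001
) -> VoxelStatMap:
    """Partial F maps for each named feature group."""
    statistic = {}
    significant = {}
    for name, cols in groups.items():
        F, p, sig = group_f_test(fit, cols, alpha=alpha)
        statistic[name] = F
        significant[name] = sig
    return VoxelStatMap(statistic, significant, alpha, "f_test")


# ---------------------------------------------------------------------------
# Cross-validated sparse encoding


def _lasso_group_stats(
    y: np.ndarray,
    Z: np.ndarray,
    group_cols: dict[str, np.ndarray],
    n_folds: int,
    seed: int,
    alphas: np.ndarray,
) -> dict[str, float]:
    ysd = y.std()
    ystd = (y - y.mean()) / (ysd if ysd > 0 else 1.0)
    model = LassoCV(alphas=alphas, cv=KFold(n_folds, shuffle=True, random_state=seed),
                    max_iter=5000)
    model.fit(Z, ystd)
    w = model.coef_
    return {g: float((w[cols] ** 2).sum()) for g, cols in group_cols.items()}


def voxelwise_sparse_encoding(
    betas: np.ndarray,
    features: pd.DataFrame,
    groups: dict[str, list[str]],
    roi_labels: np.ndarray,
    n_folds: int = 12,
    n_null: int = 200,
    alpha: float = 0.001,
    seed: int = 0,
    lasso_alphas: np.ndarray | None = None,
) -> VoxelStatMap:
    """Lasso encoding at each voxel with shuffled-label nulls per ROI.

    ``betas`` is (trials, voxels); features are z-scored and the trial betas
    standardised per voxel.  The per-voxel, per-group statistic is the sum
    of squared lasso weights over that group's features; a voxel is
    significant for a group when its statistic exceeds the (1 - alpha)
    quantile of the ROI's shuffled-label null for that group.  ``n_null``
    shuffled regressions are pooled per ROI, cycling through its voxels.
    """
    B = np.asarray(betas, dtype=float)
    if B.shape[0] < n_folds:
        raise ValueError("fewer trials than folds")
    X = features.values.astype(float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    names = list(features.columns)
    group_cols = {
        g: np.array([names.index(c) for c in cols]) for g, cols in groups.items()
    }
    if lasso_alphas is None:
        lasso_alphas = np.logspace(-3, 0, 8)

    n_vox = B.shape[1]
    statistic = {g: np.zeros(n_vox) for g in groups}
    for v in range(n_vox):
        st = _lasso_group_stats(B[:, v], Z, group_cols, n_folds, seed, lasso_alphas)
        for g in groups:
            statistic[g][v] = st[g]

    rng = np.random.default_rng(seed + 1)
    significant = {g: np.zeros(n_vox, dtype=bool) for g in groups}
    for roi in np.unique(roi_labels):
        vox = np.nonzero(roi_labels == roi)[0]
        null = {g: np.empty(n_null) for g in groups}
        for i in range(n_null):
            v = vox[i % vox.size]
            yp = rng.permutation(B[:, v])
            st = _lasso_group_stats(yp, Z, group_cols, n_folds, seed, lasso_alphas)
            for g in groups:
                null[g][i] = st[g]
        for g in groups:
            thr = np.quantile(null[g], 1.0 - alpha)
            significant[g][vox] = statistic[g][vox] > thr
    return VoxelStatMap(statistic, significant, alpha, "sum_sq_weights")


# ---------------------------------------------------------------------------
# ROI profiles


@dataclass
class RoiProfile:
    proportions: pd.DataFrame  # ROI (ordered) x group
    hierarchy_index: float
    empty_rois: tuple[str, ...] = ()


def roi_proportion_profile(
    maps: VoxelStatMap,
    roi_labels: np.ndarray,
    roi_order: list[str],
    low_group: str = "low",
    high_group: str = "high",
) -> RoiProfile:
    """Per-ROI fraction of significant voxels per group, in ROI order.

    The hierarchy index is the Spearman rank correlation between ROI order
    and (high proportion - low proportion); 0 when the difference is
    constant (e.g. identical maps).
    """
    rows = {}
    empty = []
    for roi in roi_order:
        vox = roi_labels == roi
        n = int(vox.sum())
        if n == 0:
            empty.append(roi)
            rows[roi] = {g: np.nan for g in maps.significant}
            continue
        rows[roi] = {g: float(maps.significant[g][vox].mean()) for g in maps.significant}
    prop = pd.DataFrame(rows).T.loc[roi_order]

    idx = None
    if low_group in prop.columns and high_group in prop.columns:
        diff = (prop[high_group] - prop[low_group]).values
        ok = np.isfinite(diff)
        if ok.sum() >= 2 and np.std(diff[ok]) > 0:
            idx = float(stats.spearmanr(np.arange(len(diff))[ok], diff[ok])[0])
    return RoiProfile(prop, idx if idx is not None else 0.0, tuple(empty))
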