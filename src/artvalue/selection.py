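"""Group-level selection of the shared feature set.

The pipeline: (1) orthogonalise the candidate features by sparse PCA;
(2) run a group lasso over all participants jointly — one group per
component, collecting that component's coefficients across participants —
solved by monotone FISTA with backtracking, with the penalty chosen by
cross-validation on shared stimulus folds; (3) drop components active in at
most one participant, map the survivors back to original features through
the sparse loadings, de-duplicate highly correlated pairs (r^2 above
threshold keeps the feature earlier in catalog order), and finally append
the annotated high-level attributes, mirroring the two-stage procedure of
selecting low-level features first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, SparsePCA
from sklearn.model_selection import KFold


# ---------------------------------------------------------------------------
# Sparse PCA orthogonalisation


@dataclass
class SparsePcaResult:
    loadings: np.ndarray  # (n_components, n_features)
    scores: np.ndarray  # (n_samples, n_components)
    feature_names: list[str]
    dropped_components: tuple[int, ...] = field(default_factory=tuple)


def orthogonalize_sparse_pca(
    features: np.ndarray,
    n_components: int,
    sparsity: float = 1.0,
    feature_names=None,
    seed: int = 0,
) -> SparsePcaResult:
    """Sparse PCA of (z-scored) features, keeping the back-transform.

    ``sparsity`` is the l1 penalty on the loadings; 0 reduces exactly to
    ordinary PCA.  Components whose loadings are entirely zero (possible at
    high sparsity) are dropped with a warning.
    """
    X = np.asarray(features, dtype=float)
    if n_components > X.shape[1]:
        raise ValueError("n_components cannot exceed n_features")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    if sparsity == 0:
        pca = PCA(n_components=n_components, random_state=seed)
        scores = pca.fit_transform(X)
        return SparsePcaResult(pca.components_.copy(), scores, list(feature_names))
    spca = SparsePCA(n_components=n_components, alpha=sparsity, random_state=seed,
                     max_iter=500)
    scores = spca.fit_transform(X)
    load = spca.components_
    nz = np.abs(load).sum(axis=1) > 0
    dropped = tuple(int(i) for i in np.nonzero(~nz)[0])
    if dropped:
        warnings.warn(f"dropping all-zero sparse components {dropped}", stacklevel=2)
        load = load[nz]
        scores = scores[:, nz]
    return SparsePcaResult(load.copy(), scores, list(feature_names), dropped)


# ---------------------------------------------------------------------------
# Group lasso via monotone FISTA


@dataclass
class GroupLassoFit:
    coef: np.ndarray  # (n_participants, n_features)
    intercepts: np.ndarray
    lam: float
    converged: bool
    n_iter: int
    objective: float

    def group_norms(self) -> np.ndarray:
        return np.linalg.norm(self.coef, axis=0)

    def active_groups(self, tol: float = 1e-8) -> np.ndarray:
        return self.group_norms() > tol

    def active_by_participant(self, tol: float = 1e-8) -> np.ndarray:
        """Boolean (n_participants, n_features) activity matrix."""
        return np.abs(self.coef) > tol


def _objective(Xs, ys, B, lam):
    smooth = 0.0
    for s, (X, y) in enumerate(zip(Xs, ys)):
        r = y - X @ B[s]
        smooth += 0.5 * float(r @ r)
    return smooth + lam * float(np.linalg.norm(B, axis=0).sum())


def _grad(Xs, ys, B):
    G = np.zeros_like(B)
    for s, (X, y) in enumerate(zip(Xs, ys)):
        G[s] = X.T @ (X @ B[s] - y)
    return G


def _smooth_val(Xs, ys, B):
    v = 0.0
    for s, (X, y) in enumerate(zip(Xs, ys)):
        r = y - X @ B[s]
        v += 0.5 * float(r @ r)
    return v


def _prox(B, thresh):
    norms = np.linalg.norm(B, axis=0)
    scale = np.maximum(0.0, 1.0 - thresh / np.maximum(norms, 1e-300))
    return B * scale[None, :]


def group_lasso_select(
    designs,
    targets,
    lam: float,
    max_iter: int = 10000,
    tol: float = 1e-8,
    backtrack_factor: float = 0.5,
) -> GroupLassoFit:
    """Joint group lasso across participants, one group per feature.

    Minimises 0.5 * sum_s ||y_s - X_s b_s||^2 + lam * sum_j ||B[:, j]||_2
    by monotone FISTA: a proximal gradient step with backtracking line
    search, an acceleration step, and acceptance of the accelerated point
    only when it does not increase the objective (so the objective sequence
    is non-increasing).  Targets are centred internally; the returned
    intercepts are the target means.
    """
    Xs = [np.asarray(X, dtype=float) for X in designs]
    ys_raw = [np.asarray(y, dtype=float) for y in targets]
    intercepts = np.array([y.mean() for y in ys_raw])
    ys = [y - y.mean() for y in ys_raw]
    S = len(Xs)
    p = Xs[0].shape[1]
    if any(X.shape[1] != p for X in Xs):
        raise ValueError("all participants must share design columns")

    B = np.zeros((S, p))
    Z = B.copy()
    t_momentum = 1.0
    step = 1.0
    obj = _objective(Xs, ys, B, lam)
    converged = False
    it = 0

    def prox_step(point):
        """Backtracking proximal gradient step from ``point``."""
        nonlocal step
        g = _grad(Xs, ys, point)
        f0 = _smooth_val(Xs, ys, point)
        while True:
            cand = _prox(point - step * g, lam * step)
            diff = cand - point
            lhs = _smooth_val(Xs, ys, cand)
            rhs = f0 + float((g * diff).sum()) + float((diff * diff).sum()) / (2 * step)
            if lhs <= rhs + 1e-12 or step < 1e-16:
                return cand
            step *= backtrack_factor

    for it in range(1, max_iter + 1):
        cand = prox_step(Z)
        cand_obj = _objective(Xs, ys, cand, lam)
        if cand_obj > obj:
            # accelerated step overshot: restart momentum and descend from B
            t_momentum = 1.0
            cand = prox_step(B)
            cand_obj = _objective(Xs, ys, cand, lam)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_momentum**2)) / 2.0
        Z = cand + ((t_momentum - 1.0) / t_next) * (cand - B)
        rel = abs(obj - cand_obj) / max(abs(obj), 1e-12)
        B, obj = cand, cand_obj
        t_momentum = t_next
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("group lasso did not converge", stacklevel=2)
    return GroupLassoFit(B, intercepts, lam, converged, it, obj)


def lambda_max(designs, targets) -> float:
    """Smallest penalty at which every group is zero."""
    G = _grad(
        [np.asarray(X, float) for X in designs],
        [np.asarray(y, float) - np.mean(y) for y in targets],
        np.zeros((len(designs), np.asarray(designs[0]).shape[1])),
    )
    return float(np.linalg.norm(G, axis=0).max())


def group_lasso_cv(
    designs,
    targets,
    n_folds: int = 5,
    n_lambdas: int = 30,
    lambda_range: tuple[float, float] = (1e-4, 1.0),
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-7,
    rule: str = "1se",
    scoring: str = "relaxed",
) -> tuple[GroupLassoFit, float, np.ndarray]:
    """Choose the penalty by stimulus-level folds shared across participants.

    The grid is log-spaced over ``lambda_range`` times lambda_max.  With the
    default "relaxed" scoring, each penalty is scored by the held-out error
    of an unpenalised least-squares refit on that penalty's active groups —
    the relaxed-lasso convention, which makes the CV curve sensitive to
    spurious inclusions and is markedly better at exact support recovery;
    ``scoring="penalized"`` uses the shrunken coefficients directly.  With
    the default one-standard-error rule the largest penalty whose mean CV
    error is within one SE of the minimum is chosen; ``rule="min"`` takes
    the error-minimising penalty.  Returns the refit at the chosen penalty,
    that penalty, and the per-fold CV error matrix (folds x lambdas).
    """
    Xs = [np.asarray(X, float) for X in designs]
    ys = [np.asarray(y, float) for y in targets]
    n = Xs[0].shape[0]
    if any(X.shape[0] != n for X in Xs):
        raise ValueError("CV requires shared stimulus rows across participants")
    lmax = lambda_max(Xs, ys)
    grid = np.exp(
        np.linspace(np.log(lambda_range[0] * lmax), np.log(lambda_range[1] * lmax),
                    n_lambdas)
    )[::-1]  # descending: large lambda first
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = np.zeros((n_folds, n_lambdas))
    for f, (tr, te) in enumerate(kf.split(np.arange(n))):
        Xtr = [X[tr] for X in Xs]
        Xte = [X[te] for X in Xs]
        for i, lam in enumerate(grid):
            fit = group_lasso_select(Xtr, [y[tr] for y in ys], lam,
                                     max_iter=max_iter, tol=tol)
            if scoring == "relaxed":
                act = fit.group_norms() > 1e-8
                for s in range(len(Xs)):
                    mu = ys[s][tr].mean()
                    if act.sum() == 0:
                        pred = np.full(te.size, mu)
                    else:
                        b, *_ = np.linalg.lstsq(
                            Xtr[s][:, act], ys[s][tr] - mu, rcond=None
                        )
                        pred = Xte[s][:, act] @ b + mu
                    errs[f, i] += float(((ys[s][te] - pred) ** 2).mean())
            else:
                for s in range(len(Xs)):
                    pred = Xte[s] @ fit.coef[s] + fit.intercepts[s]
                    errs[f, i] += float(((ys[s][te] - pred) ** 2).mean())
    mean = errs.mean(axis=0)
    i_min = int(np.argmin(mean))
    if rule == "1se":
        se = errs.std(axis=0, ddof=1) / np.sqrt(n_folds)
        ok = np.nonzero(mean <= mean[i_min] + se[i_min])[0]
        i_best = int(ok.min())  # grid is descending: smallest index = largest lambda
    else:
        i_best = i_min
    best = float(grid[i_best])
    final = group_lasso_select(Xs, ys, best, tol=tol)
    return final, best, errs


# ---------------------------------------------------------------------------
# Final shared set


@dataclass
class SharedFeatureSet:
    names: list[str]
    levels: dict[str, str]

    def __len__(self) -> int:
        return len(self.names)


def finalize_shared_set(
    fit: GroupLassoFit,
    spca: SparsePcaResult,
    feature_matrix: np.ndarray,
    catalog_order: list[str],
    high_level_names: list[str] | None = None,
    min_participants: int = 2,
    r2_threshold: float = 0.5,
    loading_fraction: float = 0.3,
    activity_tol: float = 1e-6,
) -> SharedFeatureSet:
    """Map selected components back to features and build the shared set.

    Components active in fewer than ``min_participants`` participants are
    discarded.  A surviving component contributes every feature whose
    |loading| is at least ``loading_fraction`` of that component's largest
    |loading|.  Among any feature pair with squared correlation above
    ``r2_threshold`` (on ``feature_matrix``), the one later in catalog order
    is dropped.  ``high_level_names`` are appended afterwards, completing the
    two-stage (low-level first, then annotated attributes) construction.
    """
    active_counts = fit.active_by_participant(activity_tol).sum(axis=0)
    shared_pcs = np.nonzero(active_counts >= min_participants)[0]
    if shared_pcs.size == 0:
        raise ValueError(
            "no component is shared by enough participants; revise the lambda grid"
        )

    selected: set[str] = set()
    for j in shared_pcs:
        load = np.abs(spca.loadings[j])
        keep = load >= loading_fraction * load.max()
        for name in np.array(spca.feature_names)[keep]:
            selected.add(str(name))

    ordered = [n for n in catalog_order if n in selected]
    X = np.asarray(feature_matrix, dtype=float)
    name_to_col = {n: i for i, n in enumerate(spca.feature_names)}
    kept: list[str] = []
    for name in ordered:
        xi = X[:, name_to_col[name]]
        ok = True
        for other in kept:
            xo = X[:, name_to_col[other]]
            if xi.std() == 0 or xo.std() == 0:
                continue
            r = np.corrcoef(xi, xo)[0, 1]
            if r * r > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(name)

    levels = {n: "low" for n in kept}
    for n in high_level_names or []:
        if n not in kept:
            kept.append(n)
        levels[n] = "high"
    return SharedFeatureSet(kept, levels)
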