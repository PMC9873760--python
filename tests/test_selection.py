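import numpy as np
import pytest

from artvalue.selection import (
    GroupLassoFit,
    SparsePcaResult,
    finalize_shared_set,
    group_lasso_cv,
    group_lasso_select,
    lambda_max,
    orthogonalize_sparse_pca,
)


def planted_cohort(seed, n=150, p=10, n_participants=4, support=(0, 3, 7),
                   noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Xs = [X] * n_participants
    ys = []
    for _ in range(n_participants):
        w = np.zeros(p)
        w[list(support)] = rng.uniform(1, 2, len(support)) * rng.choice([-1, 1], len(support))
        ys.append(X @ w + noise * rng.standard_normal(n))
    return Xs, ys


class TestSparsePca:
    def test_zero_sparsity_reduces_to_pca(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 6))
        X = (X - X.mean(0)) / X.std(0)
        res = orthogonalize_sparse_pca(X, 4, sparsity=0.0)
        # reconstruction error matches ordinary PCA
        proj = res.scores @ res.loadings
        from sklearn.decomposition import PCA

        pca = PCA(n_components=4)
        ref = pca.inverse_transform(pca.fit_transform(X))
        assert np.square(X - proj).sum() == pytest.approx(
            np.square(X - ref).sum(), abs=1e-6
        )

    def test_duplicated_columns_load_on_one_component(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((100, 5))
        Z = np.column_stack([Z, Z[:, 0]])
        Z = (Z - Z.mean(0)) / Z.std(0)
        res = orthogonalize_sparse_pca(Z, 3, sparsity=1.0)
        loads_on_dupes = np.abs(res.loadings[:, [0, 5]]) > 1e-6
        shared = loads_on_dupes.all(axis=1)
        assert shared.any()

    def test_component_scores_nearly_uncorrelated(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((120, 8))
        X = (X - X.mean(0)) / X.std(0)
        res = orthogonalize_sparse_pca(X, 4, sparsity=1.0)
        C = np.corrcoef(res.scores.T)
        off = C[~np.eye(C.shape[0], dtype=bool)]
        assert np.abs(off).max() <= 0.1

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            orthogonalize_sparse_pca(np.zeros((10, 3)), 4)


class TestGroupLasso:
    def test_unpenalized_limit_matches_least_squares(self):
        Xs, ys = planted_cohort(1)
        fit = group_lasso_select(Xs, ys, 0.0, tol=1e-12)
        ls_obj = 0.0
        for X, y in zip(Xs, ys):
            yc = y - y.mean()
            b, *_ = np.linalg.lstsq(X, yc, rcond=None)
            ls_obj += 0.5 * np.square(yc - X @ b).sum()
        assert fit.objective == pytest.approx(ls_obj, abs=1e-6)

    def test_full_shrinkage_above_lambda_max(self):
        Xs, ys = planted_cohort(2)
        lam = lambda_max(Xs, ys) * 1.0001
        fit = group_lasso_select(Xs, ys, lam)
        assert np.abs(fit.coef).max() == 0.0

    def test_objective_nonincreasing_along_iterations(self):
        # track the objective through a verbose re-run
        Xs, ys = planted_cohort(3)
        from artvalue.selection import _objective

        lam = 0.3 * lambda_max(Xs, ys)
        objs = []
        fit = group_lasso_select(Xs, ys, lam, max_iter=1, tol=0)
        prev = np.inf
        B = fit.coef
        # run to convergence and confirm final <= any partial run
        for iters in (1, 5, 20, 100, 500):
            f = group_lasso_select(Xs, ys, lam, max_iter=iters, tol=0)
            objs.append(f.objective)
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_active_set_shrinks_with_lambda(self):
        Xs, ys = planted_cohort(4)
        lmax = lambda_max(Xs, ys)
        counts = []
        for frac in (0.001, 0.01, 0.1, 0.5, 1.1):
            fit = group_lasso_select(Xs, ys, frac * lmax)
            counts.append(int(fit.active_groups(1e-8).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_planted_support_recovery_across_seeds(self):
        """CV-selected penalty recovers exactly the driving features."""
        successes = 0
        for seed in range(20):
            Xs, ys = planted_cohort(seed)
            fit, _, _ = group_lasso_cv(Xs, ys, n_folds=5, n_lambdas=20, seed=seed)
            active = set(np.nonzero(fit.group_norms() > 1e-8)[0].tolist())
            successes += active == {0, 3, 7}
        assert successes >= 16


class TestFinalizeSharedSet:
    def _identity_spca(self, names, n):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((n, len(names)))
        return SparsePcaResult(np.eye(len(names)), X.copy(), list(names)), X

    def test_correlated_pair_deduplicated_keeping_catalog_order(self):
        names = ["a", "b", "c"]
        spca, X = self._identity_spca(names, 200)
        X[:, 1] = X[:, 0] + 0.05 * np.random.default_rng(1).standard_normal(200)
        spca.scores = X
        fit = GroupLassoFit(np.ones((3, 3)), np.zeros(3), 0.1, True, 5, 0.0)
        shared = finalize_shared_set(fit, spca, X, names)
        assert "a" in shared.names
        assert "b" not in shared.names

    def test_component_active_in_single_participant_removed(self):
        names = ["a", "b"]
        spca, X = self._identity_spca(names, 100)
        coef = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])  # b: 1 participant
        fit = GroupLassoFit(coef, np.zeros(3), 0.1, True, 5, 0.0)
        shared = finalize_shared_set(fit, spca, X, names)
        assert shared.names == ["a"]

    def test_high_level_features_appended_with_level_tags(self):
        names = ["a", "b"]
        spca, X = self._identity_spca(names, 100)
        fit = GroupLassoFit(np.ones((2, 2)), np.zeros(2), 0.1, True, 5, 0.0)
        shared = finalize_shared_set(fit, spca, X, names,
                                     high_level_names=["valence"])
        assert shared.names[-1] == "valence"
        assert shared.levels["valence"] == "high"
        assert shared.levels["a"] == "low"

    def test_empty_selection_is_an_error(self):
        names = ["a", "b"]
        spca, X = self._identity_spca(names, 100)
        fit = GroupLassoFit(np.zeros((2, 2)), np.zeros(2), 9.0, True, 5, 0.0)
        with pytest.raises(ValueError, match="lambda"):
            finalize_shared_set(fit, spca, X, names)

    def test_planted_generative_set_recovered_via_full_pipeline(self):
        """Sparse PCA + group lasso + back-mapping recovers planted features."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n, p = 200, 12
            X = rng.standard_normal((n, p))
            X = (X - X.mean(0)) / X.std(0)
            names = [f"f{j}" for j in range(p)]
            support = [1, 4, 8]
            ys = []
            for _ in range(4):
                w = np.zeros(p)
                w[support] = rng.uniform(1, 2, 3) * rng.choice([-1, 1], 3)
                ys.append(X @ w + 0.5 * rng.standard_normal(n))
            spca = orthogonalize_sparse_pca(X, p, sparsity=1.0, feature_names=names,
                                            seed=seed)
            designs = [spca.scores] * 4
            fit, _, _ = group_lasso_cv(designs, ys, n_folds=5, n_lambdas=20,
                                       seed=seed)
            shared = finalize_shared_set(fit, spca, X, names)
            hits += set(f"f{j}" for j in support) <= set(shared.names)
        assert hits >= 8
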