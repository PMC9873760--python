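import numpy as np
import pandas as pd
import pytest

from artvalue.bold_sim import RoiSpec, default_rois, make_bold
from artvalue.encoding import (
    VoxelStatMap,
    feature_glm,
    group_f_maps,
    roi_proportion_profile,
    voxelwise_sparse_encoding,
)
from artvalue.glm import estimate_trial_betas
from artvalue.synthetic import make_design

ROI_ORDER = ["V1", "V2", "V4", "LO", "PHC"]


def synthetic_session(seed, n_voxels=20, runs=4, trials=25, coupling=0.8,
                      signal=1.0, rois=None):
    design, _ = make_design(runs=runs, trials_per_run=trials, seed=seed)
    rng = np.random.default_rng(seed + 1000)
    n_tr = len(design.trials)
    cols = [f"low{i}" for i in range(5)] + [f"high{i}" for i in range(3)]
    feats = pd.DataFrame(rng.standard_normal((n_tr, 8)), columns=cols)
    levels = {c: ("low" if c.startswith("low") else "high") for c in cols}
    ratings = feats.values @ rng.standard_normal(8) + rng.standard_normal(n_tr)
    if rois is None:
        rois = [
            RoiSpec(n, "feature", n_voxels, g)
            for n, g in zip(ROI_ORDER, [0.1, 0.3, 0.5, 0.7, 0.9])
        ] + [
            RoiSpec("PPC", "integrator", n_voxels, 0.5, True),
            RoiSpec("lPFC", "integrator", n_voxels, 0.5, True),
            RoiSpec("mPFC", "value", n_voxels, 0.0, True),
        ]
    bold = make_bold(design, feats, levels, ratings, rois=rois,
                     coupling_strength=coupling, signal_scale=signal,
                     seed=seed + 2000)
    return design, feats, levels, ratings, bold


class TestGlmRouteHierarchy:
    def test_planted_gradient_yields_high_hierarchy_index(self):
        hits = 0
        for seed in range(20):
            design, feats, levels, ratings, bold = synthetic_session(seed)
            fit = feature_glm(bold, design, feats, nuisance=bold.nuisance)
            groups = {
                "low": [c for c in feats if levels[c] == "low"],
                "high": [c for c in feats if levels[c] == "high"],
            }
            maps = group_f_maps(fit, groups)
            prof = roi_proportion_profile(maps, bold.roi_labels, ROI_ORDER)
            hits += prof.hierarchy_index >= 0.8
        assert hits >= 18

    def test_rating_regressor_leaves_hierarchy_unchanged(self):
        """Adding the rating to the model must not disturb the planted
        feature-group hierarchy (the augmented-model control)."""
        design, feats, levels, ratings, bold = synthetic_session(3)
        groups = {
            "low": [c for c in feats if levels[c] == "low"],
            "high": [c for c in feats if levels[c] == "high"],
        }
        base = group_f_maps(feature_glm(bold, design, feats,
                                        nuisance=bold.nuisance), groups)
        feats_rating = feats.copy()
        feats_rating["rating"] = ratings
        aug = group_f_maps(feature_glm(bold, design, feats_rating,
                                       nuisance=bold.nuisance), groups)
        p0 = roi_proportion_profile(base, bold.roi_labels, ROI_ORDER)
        p1 = roi_proportion_profile(aug, bold.roi_labels, ROI_ORDER)
        assert p1.hierarchy_index >= 0.8
        diff = (p0.proportions - p1.proportions).abs().values
        assert np.nanmean(diff) < 0.15

    def test_identical_maps_give_zero_index(self):
        sig = {"low": np.ones(50, bool), "high": np.ones(50, bool)}
        maps = VoxelStatMap({"low": np.ones(50), "high": np.ones(50)}, sig,
                            0.001, "f_test")
        labels = np.repeat(ROI_ORDER, 10)
        prof = roi_proportion_profile(maps, labels, ROI_ORDER)
        assert prof.hierarchy_index == 0.0

    def test_proportions_bounded_and_empty_roi_flagged(self):
        sig = {"low": np.zeros(20, bool), "high": np.ones(20, bool)}
        maps = VoxelStatMap({"low": np.zeros(20), "high": np.ones(20)}, sig,
                            0.001, "f_test")
        labels = np.repeat(["A", "B"], 10)
        prof = roi_proportion_profile(maps, labels, ["A", "B", "C"])
        assert prof.empty_rois == ("C",)
        vals = prof.proportions.loc[["A", "B"]].values
        assert ((vals >= 0) & (vals <= 1)).all()


class TestSparseEncodingRoute:
    @pytest.fixture(scope="class")
    def session(self):
        rois = [
            RoiSpec("V1", "feature", 12, 0.0),
            RoiSpec("PHC", "feature", 12, 1.0),
        ]
        design, feats, levels, ratings, bold = synthetic_session(
            11, rois=rois, runs=4, trials=25, signal=1.5
        )
        betas = estimate_trial_betas(bold.data, design, bold.nuisance)
        return feats, levels, bold, betas

    def test_extreme_gradient_separates_groups(self, session):
        feats, levels, bold, betas = session
        groups = {
            "low": [c for c in feats if levels[c] == "low"],
            "high": [c for c in feats if levels[c] == "high"],
        }
        maps = voxelwise_sparse_encoding(
            betas, feats, groups, bold.roi_labels, n_folds=12, n_null=120,
            alpha=0.01, seed=0,
        )
        v1 = bold.roi_labels == "V1"
        phc = bold.roi_labels == "PHC"
        assert maps.significant["low"][v1].mean() > maps.significant["high"][v1].mean()
        assert maps.significant["high"][phc].mean() > maps.significant["low"][phc].mean()

    def test_statistic_invariant_to_feature_column_order(self, session):
        feats, levels, bold, betas = session
        groups = {"low": [c for c in feats if levels[c] == "low"]}
        a = voxelwise_sparse_encoding(betas[:, :4], feats, groups,
                                      bold.roi_labels[:4], n_null=10, seed=0)
        perm = feats[list(feats.columns[::-1])]
        b = voxelwise_sparse_encoding(betas[:, :4], perm, groups,
                                      bold.roi_labels[:4], n_null=10, seed=0)
        # coordinate descent is order-dependent only at solver tolerance
        np.testing.assert_allclose(a.statistic["low"], b.statistic["low"],
                                   rtol=1e-3)

    def test_shuffled_observations_rarely_significant(self, session):
        feats, levels, bold, betas = session
        rng = np.random.default_rng(5)
        shuffled = betas[rng.permutation(betas.shape[0])]
        groups = {"all": list(feats.columns)}
        maps = voxelwise_sparse_encoding(
            shuffled, feats, groups, bold.roi_labels, n_folds=6, n_null=100,
            alpha=0.01, seed=1,
        )
        assert maps.significant["all"].mean() <= 0.15

    def test_too_few_trials_raises(self, session):
        feats, levels, bold, betas = session
        with pytest.raises(ValueError, match="folds"):
            voxelwise_sparse_encoding(betas[:5], feats, {"all": list(feats)},
                                      bold.roi_labels, n_folds=12)
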