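import numpy as np
import pandas as pd
import pytest

from artvalue.features import compute_blur, compute_segment_features
from artvalue.raster import RasterImage
from artvalue.segmentation import Segmentation
from artvalue.synthetic import (
    make_annotations,
    make_design,
    make_ratings,
    make_stimulus_images,
)


class TestStimulusImages:
    def test_deterministic_given_seed(self):
        a = make_stimulus_images(20, seed=3)
        b = make_stimulus_images(20, seed=3)
        for x, y in zip(a.images, b.images):
            assert (x.pixels == y.pixels).all()
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_symmetric_flag_produces_zero_horizontal_mse(self):
        stim = make_stimulus_images(40, seed=1, p_symmetric=1.0,
                                    blur_sigmas=(0.0,))
        for img in stim.images[:10]:
            whole = Segmentation(np.zeros(img.pixels.shape[:2], dtype=int), "srm")
            f = compute_segment_features(img, whole, 0)
            assert f["h_symmetry"] == pytest.approx(0.0, abs=1e-12)

    def test_blur_reduces_the_blur_score(self):
        sharp = make_stimulus_images(15, seed=2, blur_sigmas=(0.0,))
        soft = make_stimulus_images(15, seed=2, blur_sigmas=(4.0,))
        sharper = sum(
            compute_blur(a) > compute_blur(b)
            for a, b in zip(sharp.images, soft.images)
        )
        assert sharper >= 13

    def test_truth_table_matches_images(self):
        stim = make_stimulus_images(10, seed=4)
        assert len(stim.truth) == 10
        assert stim.truth["largest_segment_fraction"].between(0, 1).all()


class TestAnnotations:
    def test_noiseless_annotations_are_linear_in_low_level(self):
        rng = np.random.default_rng(0)
        low = pd.DataFrame(rng.standard_normal((100, 6)))
        ann, _ = make_annotations(low, noise_sd=0.0, seed=1)
        cont = ann[["concreteness", "dynamics", "temperature", "valence"]]
        Z = (low - low.mean()) / low.std(ddof=0)
        for col in cont:
            resid = cont[col] - Z.values @ np.linalg.lstsq(
                Z.values, cont[col], rcond=None
            )[0]
            assert np.square(resid).sum() == pytest.approx(0.0, abs=1e-16)

    def test_heavy_noise_destroys_reconstruction(self):
        rng = np.random.default_rng(1)
        low = pd.DataFrame(rng.standard_normal((200, 4)))
        ann, _ = make_annotations(low, noise_sd=50.0, seed=2)
        Z = (low - low.mean()) / low.std(ddof=0)
        y = ann["concreteness"].values
        b = np.linalg.lstsq(Z.values, y - y.mean(), rcond=None)[0]
        r2 = 1 - np.square(y - y.mean() - Z.values @ b).sum() / np.square(
            y - y.mean()
        ).sum()
        assert r2 < 0.2

    def test_presence_person_is_binary(self):
        rng = np.random.default_rng(2)
        low = pd.DataFrame(rng.standard_normal((50, 3)))
        ann, _ = make_annotations(low, seed=3)
        assert set(np.unique(ann["presence_person"])) <= {0.0, 1.0}


class TestRatings:
    def test_single_feature_taste_gives_monotone_ratings(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame({"f": np.sort(rng.standard_normal(200))})
        w = pd.DataFrame({"f": [2.0]})
        ds = make_ratings(feats, weights=w, noise_sd=0.0, seed=1)
        r = ds.ratings.iloc[0].values
        assert (np.diff(r) >= 0).all()

    def test_ratings_on_the_0_3_scale_with_balanced_quartiles(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(rng.standard_normal((400, 5)))
        ds = make_ratings(feats, n_participants=3, seed=2)
        vals = ds.ratings.values
        assert set(np.unique(vals)) <= {0, 1, 2, 3}
        counts = np.bincount(vals[0], minlength=4)
        assert counts.min() >= 0.2 * 400 / 4 * 2  # roughly balanced

    def test_zero_weights_give_chance_level_accuracy(self):
        from artvalue.lfs import fit_ridge_cv

        rng = np.random.default_rng(2)
        feats = pd.DataFrame(rng.standard_normal((300, 6)))
        w = pd.DataFrame(np.zeros((1, 6)), columns=feats.columns)
        ds = make_ratings(feats, weights=w, noise_sd=1.0, seed=3)
        _, cv = fit_ridge_cv(feats.values, ds.ratings.iloc[0].values, n_folds=5,
                             penalty_grid=np.array([1.0]))
        assert abs(cv.accuracy) < 0.2

    def test_default_snr_supports_weight_recovery(self):
        from artvalue.lfs import fit_ridge_cv

        rng = np.random.default_rng(3)
        feats = pd.DataFrame(
            rng.standard_normal((500, 10)), columns=[f"f{j}" for j in range(10)]
        )
        ds = make_ratings(feats, n_participants=1, noise_sd=1.0, seed=4)
        wv, _ = fit_ridge_cv(feats.values, ds.continuous.iloc[0].values,
                             n_folds=10, feature_names=feats.columns)
        west = wv.as_array(list(feats.columns))
        r = np.corrcoef(west, ds.weights.iloc[0].values)[0, 1]
        assert r >= 0.9


class TestDesign:
    def test_default_design_has_1000_unique_stimuli(self):
        design, _ = make_design(seed=0)
        assert len(design.trials) == 1000
        assert design.trials["stimulus"].nunique() == 1000

    def test_epoch_durations_and_iti_ranges(self):
        design, _ = make_design(runs=3, trials_per_run=20, seed=1)
        t = design.trials
        assert (t["stim_duration"] == 3.0).all()
        assert (t["feedback_duration"] == 0.5).all()
        assert t["iti"].between(2.0, 9.0).all()

    def test_epochs_are_disjoint_in_time(self):
        design, _ = make_design(runs=1, trials_per_run=30, seed=2)
        stim = design.stimulus_epochs(0)
        iti = design.iti_epochs(0)
        for s0, s1 in stim:
            for i0, i1 in iti:
                assert s1 <= i0 or i1 <= s0

    def test_manifest_round_trip_regenerates_identically(self, tmp_path):
        from artvalue.synthetic import load_manifest, save_manifest

        design, man = make_design(runs=2, trials_per_run=10, seed=9)
        save_manifest(man, tmp_path / "m.json")
        back = load_manifest(tmp_path / "m.json")
        regen, _ = make_design(
            runs=back["runs"], trials_per_run=back["trials_per_run"],
            seed=back["seed"], tr=back["tr"],
        )
        pd.testing.assert_frame_equal(design.trials, regen.trials)
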