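import numpy as np
import pandas as pd
import pytest

from artvalue.bold_sim import RoiSpec, make_bold
from artvalue.glm import (
    build_design_matrix,
    double_gamma_hrf,
    estimate_trial_betas,
    fit_glm,
    group_f_test,
    t_statistic,
)
from artvalue.synthetic import make_design


@pytest.fixture(scope="module")
def small_design():
    design, _ = make_design(runs=2, trials_per_run=15, seed=0)
    return design


def modulator_frame(design, k=3, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((len(design.trials), k)),
        columns=[f"m{i}" for i in range(k)],
    )


class TestHrf:
    def test_peaks_near_its_nominal_delay_with_undershoot(self):
        # the gamma-difference kernel modes just below its 6 s delay parameter
        t = np.arange(0, 32, 0.1)
        h = double_gamma_hrf(t)
        assert 4.5 <= t[np.argmax(h)] <= 6.5
        assert h.min() < 0  # undershoot
        assert h.max() == pytest.approx(1.0)

    def test_matches_external_canonical_kernel(self):
        """Cross-check against the SPM-style kernel from nilearn."""
        nilearn = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        tr = 1.12
        ours = double_gamma_hrf(np.arange(0, 32, tr / 16))
        ref = nilearn.spm_hrf(tr, oversampling=16, time_length=32)
        ref = ref / ref.max()
        n = min(len(ours), len(ref))
        r = np.corrcoef(ours[:n], ref[:n])[0, 1]
        assert r > 0.99


class TestDesignMatrix:
    def test_single_modulator_column_is_convolved_and_centred(self, small_design):
        mods = modulator_frame(small_design, k=1)
        dm = build_design_matrix(small_design, mods)
        assert "m0" in dm.names
        assert dm.matrix.shape[0] == small_design.n_scans_total

    def test_identical_modulators_raise_rank_error(self, small_design):
        mods = modulator_frame(small_design, k=1)
        mods["m1"] = mods["m0"]
        with pytest.raises(ValueError, match="rank"):
            build_design_matrix(small_design, mods)

    def test_modulator_scaling_leaves_t_statistics_unchanged(self, small_design):
        rng = np.random.default_rng(1)
        mods = modulator_frame(small_design, k=1, seed=1)
        dm1 = build_design_matrix(small_design, mods)
        dm2 = build_design_matrix(small_design, mods * 7.3)
        y = (
            2.0 * dm1.column("m0")
            + rng.standard_normal(dm1.n_timepoints)
        )[None, :]
        t1 = t_statistic(fit_glm(y, dm1), "m0")
        t2 = t_statistic(fit_glm(y, dm2), "m0")
        assert t1[0] == pytest.approx(t2[0], rel=1e-9)

    def test_boxcar_mode_differs_from_stick_mode(self, small_design):
        mods = modulator_frame(small_design, k=1)
        a = build_design_matrix(small_design, mods, mode="onset_stick")
        b = build_design_matrix(small_design, mods, mode="epoch_boxcar")
        assert not np.allclose(a.column("m0"), b.column("m0"))


class TestTrialBetas:
    def test_known_amplitudes_recovered_in_noiseless_voxel(self, small_design):
        rng = np.random.default_rng(2)
        amps = rng.uniform(0.5, 2.0, len(small_design.trials))
        dm = build_design_matrix(
            small_design, pd.DataFrame({"amp": amps - amps.mean()})
        )
        # voxel built directly from per-trial convolved sticks
        from artvalue.glm import _convolve_run

        run_ids = sorted(small_design.trials["run"].unique())
        parts = []
        for r in run_ids:
            sub = small_design.trials[small_design.trials["run"] == r]
            parts.append(
                _convolve_run(
                    sub["stim_onset"].values,
                    np.zeros(len(sub)),
                    amps[sub.index],
                    small_design.run_n_scans(r),
                    small_design.tr,
                )
            )
        voxel = np.concatenate(parts)[None, :]
        betas = estimate_trial_betas(voxel, small_design)
        assert np.allclose(betas[:, 0], amps, atol=1e-6)

    def test_noise_voxel_betas_are_centred(self, small_design):
        rng = np.random.default_rng(3)
        voxel = rng.standard_normal((1, small_design.n_scans_total))
        betas = estimate_trial_betas(voxel, small_design)
        se = betas[:, 0].std() / np.sqrt(len(betas))
        assert abs(betas[:, 0].mean()) < 3 * se + 0.05

    def test_drift_absorbed_by_nuisance(self, small_design):
        rng = np.random.default_rng(4)
        amps = rng.uniform(0.5, 2.0, len(small_design.trials))
        from artvalue.glm import _convolve_run

        run_ids = sorted(small_design.trials["run"].unique())
        parts = []
        for r in run_ids:
            sub = small_design.trials[small_design.trials["run"] == r]
            parts.append(
                _convolve_run(sub["stim_onset"].values, np.zeros(len(sub)),
                              amps[sub.index], small_design.run_n_scans(r),
                              small_design.tr)
            )
        clean = np.concatenate(parts)
        drift = np.linspace(0, 1, clean.size)
        nuis = pd.DataFrame({"drift": drift})
        b1 = estimate_trial_betas(clean[None, :], small_design)
        b2 = estimate_trial_betas((clean + 5 * drift)[None, :], small_design,
                                  nuisance=nuis)
        assert np.allclose(b1[:, 0], b2[:, 0], atol=1e-6)


class TestGroupFTest:
    def _fit(self, design, y, mods):
        dm = build_design_matrix(design, mods)
        return fit_glm(y, dm)

    def test_f_equals_squared_t_for_single_column_group(self, small_design):
        rng = np.random.default_rng(5)
        mods = modulator_frame(small_design, k=2, seed=5)
        dm = build_design_matrix(small_design, mods)
        y = (dm.column("m0") + rng.standard_normal(dm.n_timepoints))[None, :]
        fit = fit_glm(y, dm)
        F, _, _ = group_f_test(fit, ["m0"])
        t = t_statistic(fit, "m0")
        assert F[0] == pytest.approx(t[0] ** 2, rel=1e-9)

    def test_planted_group_detected_not_the_other(self, small_design):
        rng = np.random.default_rng(6)
        mods = modulator_frame(small_design, k=4, seed=6)
        dm = build_design_matrix(small_design, mods)
        n_vox = 50
        signal = dm.column("m0") + 0.8 * dm.column("m1")
        Y = 3 * signal[None, :] + rng.standard_normal((n_vox, dm.n_timepoints))
        fit = fit_glm(Y, dm)
        _, _, sig_low = group_f_test(fit, ["m0", "m1"], alpha=0.001)
        _, _, sig_high = group_f_test(fit, ["m2", "m3"], alpha=0.001)
        assert sig_low.sum() >= 48
        assert sig_high.sum() <= 2

    def test_null_rejection_rate_calibrated(self, small_design):
        rng = np.random.default_rng(7)
        mods = modulator_frame(small_design, k=3, seed=7)
        dm = build_design_matrix(small_design, mods)
        n_vox = 5000
        Y = rng.standard_normal((n_vox, dm.n_timepoints))
        fit = fit_glm(Y, dm)
        for alpha in (0.05, 0.01, 0.001):
            _, _, sig = group_f_test(fit, ["m0", "m1", "m2"], alpha=alpha)
            rate = sig.mean()
            se = np.sqrt(alpha * (1 - alpha) / n_vox)
            assert abs(rate - alpha) < 3 * se + 1e-4

    def test_unknown_group_member_raises(self, small_design):
        mods = modulator_frame(small_design, k=2)
        dm = build_design_matrix(small_design, mods)
        fit = fit_glm(np.zeros((1, dm.n_timepoints)), dm)
        with pytest.raises(KeyError):
            group_f_test(fit, ["nope"])
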