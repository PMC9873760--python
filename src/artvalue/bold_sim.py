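"""Synthetic multi-region BOLD with a planted low/high feature gradient.

Ordered "visual" ROIs weight low-level versus high-level feature signal
according to a planted gradient g (the share of high-level signal): early
regions carry mostly low-level modulation, late regions mostly high-level.
Two "integrator" ROIs (posterior-parietal and lateral-prefrontal analogues)
mix both; one "value" ROI tracks the continuous rating.  During stimulus
epochs only, a shared latent noise term is injected into the value ROI and
the integrator ROIs, creating the stimulus-locked noise coupling that a
psychophysiological-interaction analysis detects.  Noise is AR(1) plus
white; the hemodynamic response is the canonical double-gamma kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .glm import _convolve_run
from .synthetic import ExperimentDesign


@dataclass
class RoiSpec:
    name: str
    kind: str  # "feature" | "integrator" | "value"
    n_voxels: int
    g: float  # share of high-level signal (feature/integrator ROIs)
    coupled: bool = False  # receives the stimulus-gated latent


def default_rois(n_voxels: int = 40) -> list[RoiSpec]:
    """Five ordered feature ROIs with gradient g = 0.1 ... 0.9, two coupled
    integrator ROIs, and one value ROI."""
    grad = [0.1, 0.3, 0.5, 0.7, 0.9]
    names = ["V1", "V2", "V4", "LO", "PHC"]
    rois = [RoiSpec(n, "feature", n_voxels, g) for n, g in zip(names, grad)]
    rois.append(RoiSpec("PPC", "integrator", n_voxels, 0.5, coupled=True))
    rois.append(RoiSpec("lPFC", "integrator", n_voxels, 0.5, coupled=True))
    rois.append(RoiSpec("mPFC", "value", n_voxels, 0.0, coupled=True))
    return rois


@dataclass
class SyntheticGroundTruth:
    rois: list[RoiSpec]
    coupling_strength: float
    signal_scale: float
    noise_sd: float
    ar1_rho: float
    seed: int
    voxel_g: np.ndarray = field(default=None)  # per-voxel high-level share
    manifest: dict = field(default_factory=dict)


@dataclass
class BoldDataset:
    data: np.ndarray  # (voxels, timepoints)
    tr: float
    roi_labels: np.ndarray  # str per voxel
    nuisance: pd.DataFrame
    run_lengths: list[int]
    truth: SyntheticGroundTruth | None = None

    def roi_mask(self, name: str) -> np.ndarray:
        return self.roi_labels == name

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]


def _epoch_boxcar(epochs: np.ndarray, n_scans: int, tr: float) -> np.ndarray:
    t = np.arange(n_scans) * tr
    box = np.zeros(n_scans)
    for a, b in epochs:
        box[(t >= a) & (t < b)] = 1.0
    return box


def make_bold(
    design: ExperimentDesign,
    features: pd.DataFrame,
    levels: dict[str, str],
    ratings_continuous: np.ndarray,
    rois: list[RoiSpec] | None = None,
    coupling_strength: float = 0.8,
    signal_scale: float = 1.0,
    noise_sd: float = 1.0,
    ar1_rho: float = 0.3,
    g_jitter: float = 0.05,
    nuisance_amplitude: float = 0.2,
    seed: int = 0,
) -> BoldDataset:
    """Simulate voxel timecourses for one participant.

    ``features`` has one row per trial (the shared feature values of the
    stimulus shown), tagged low/high by ``levels``; ``ratings_continuous``
    is the trial-wise continuous value.  Each feature-ROI voxel's
    stimulus-onset regressor is parametrically modulated by a voxel-specific
    mixture of low-level (weight 1-g) and high-level (weight g) feature
    values; value-ROI voxels are modulated by the rating.  Coupled ROIs
    share a latent noise term gated by the stimulus boxcar.
    """
    if len(features) != len(design.trials):
        raise ValueError("features rows must align to design trials")
    if len(ratings_continuous) != len(design.trials):
        raise ValueError("ratings must align to design trials")
    rng = np.random.default_rng(seed)
    rois = rois if rois is not None else default_rois()
    tr = design.tr
    run_ids = sorted(design.trials["run"].unique())
    run_lengths = [design.run_n_scans(r) for r in run_ids]
    n_total = sum(run_lengths)

    X = features.values.astype(float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    low_idx = [i for i, c in enumerate(features.columns) if levels[c] == "low"]
    high_idx = [i for i, c in enumerate(features.columns) if levels[c] == "high"]
    v = np.asarray(ratings_continuous, dtype=float)
    v = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)

    # stimulus-gated latent, one stream per run
    latent = np.concatenate(
        [
            _epoch_boxcar(design.stimulus_epochs(r), n_scans, tr)
            * rng.standard_normal(n_scans)
            for r, n_scans in zip(run_ids, run_lengths)
        ]
    )

    def convolve_modulator(amplitudes: np.ndarray) -> np.ndarray:
        parts = []
        for r, n_scans in zip(run_ids, run_lengths):
            sub = design.trials[design.trials["run"] == r]
            amp = amplitudes[sub.index.values]
            parts.append(
                _convolve_run(sub["stim_onset"].values, np.zeros(len(sub)), amp,
                              n_scans, tr)
            )
        return np.concatenate(parts)

    # smooth motion-like nuisance streams, mildly present in the data
    nuis = np.column_stack(
        [
            gaussian_filter1d(np.cumsum(rng.standard_normal(n_total)), 10.0)
            for _ in range(6)
        ]
    )
    nuis = (nuis - nuis.mean(axis=0)) / np.maximum(nuis.std(axis=0), 1e-12)
    nuisance = pd.DataFrame(nuis, columns=[f"motion_{i}" for i in range(6)])

    voxels = []
    labels = []
    voxel_g = []
    for roi in rois:
        for _ in range(roi.n_voxels):
            if roi.kind == "value":
                mod = v
                g_v = np.nan
            else:
                g_v = float(np.clip(roi.g + g_jitter * rng.standard_normal(), 0.0, 1.0))
                u_low = rng.standard_normal(len(low_idx))
                u_low /= np.linalg.norm(u_low)
                u_high = rng.standard_normal(len(high_idx))
                u_high /= np.linalg.norm(u_high)
                mod = (1.0 - g_v) * Z[:, low_idx] @ u_low + g_v * Z[:, high_idx] @ u_high
            sig = signal_scale * convolve_modulator(mod)
            # AR(1) + white noise, independent across runs
            noise = np.empty(n_total)
            off = 0
            for n_scans in run_lengths:
                eps = rng.standard_normal(n_scans)
                ar = np.empty(n_scans)
                ar[0] = eps[0]
                for t_i in range(1, n_scans):
                    ar[t_i] = ar1_rho * ar[t_i - 1] + eps[t_i]
                noise[off : off + n_scans] = ar
                off += n_scans
            sig = sig + noise_sd * noise
            if roi.coupled:
                sig = sig + coupling_strength * latent
            sig = sig + nuisance_amplitude * (nuis @ rng.standard_normal(6))
            voxels.append(sig)
            labels.append(roi.name)
            voxel_g.append(g_v)

    truth = SyntheticGroundTruth(
        rois=rois,
        coupling_strength=coupling_strength,
        signal_scale=signal_scale,
        noise_sd=noise_sd,
        ar1_rho=ar1_rho,
        seed=seed,
        voxel_g=np.array(voxel_g),
        manifest={
            "generator": "make_bold", "seed": seed,
            "coupling_strength": coupling_strength,
            "signal_scale": signal_scale, "noise_sd": noise_sd,
            "ar1_rho": ar1_rho, "g_jitter": g_jitter,
            "nuisance_amplitude": nuisance_amplitude,
            "rois": [
                {"name": r.name, "kind": r.kind, "n_voxels": r.n_voxels,
                 "g": r.g, "coupled": r.coupled}
                for r in rois
            ],
        },
    )
    return BoldDataset(
        np.array(voxels), tr, np.array(labels), nuisance, run_lengths, truth
    )


# ---------------------------------------------------------------------------
# NIfTI round trip (voxels arranged in labelled blocks along one axis)


def save_nifti(dataset: BoldDataset, bold_path, mask_path) -> None:
    import nibabel as nib

    data = dataset.data[:, None, None, :].astype(np.float32)
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header["pixdim"][4] = dataset.tr
    nib.save(img, bold_path)
    uniq = list(dict.fromkeys(dataset.roi_labels))
    ids = np.array([uniq.index(l) + 1 for l in dataset.roi_labels])
    mask = nib.Nifti1Image(ids[:, None, None].astype(np.int16), affine=np.eye(4))
    mask.header.extensions.append(
        nib.nifti1.Nifti1Extension("comment", (";".join(uniq)).encode())
    )
    nib.save(mask, mask_path)


def load_nifti(bold_path, mask_path, tr: float, run_lengths: list[int]) -> BoldDataset:
    import nibabel as nib

    img = nib.load(bold_path)
    data = np.asarray(img.dataobj)[:, 0, 0, :]
    mask_img = nib.load(mask_path)
    ids = np.asarray(mask_img.dataobj)[:, 0, 0]
    names = None
    for ext in mask_img.header.extensions:
        names = ext.get_content().decode().split(";")
    labels = np.array([names[i - 1] for i in ids])
    nuisance = pd.DataFrame(index=range(data.shape[1]))
    return BoldDataset(data, tr, labels, nuisance, run_lengths)
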