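"""Psychophysiological interaction (PPI) analysis.

Tests whether feature-encoding voxels are noise-coupled to the value region
during stimulus processing: the interaction regressor is the elementwise
product of the seed (value-region) timecourse and a mean-centred
psychological boxcar (stimulus epochs, or ITI epochs for the control).  The
base model regresses out all feature and rating signals (boxcar-modulated)
plus the seed and psychological main effects, so a surviving interaction
effect reflects stimulus-locked noise correlation with the seed.  PPI here
operates at the signal level (no hemodynamic deconvolution); a deconvolved
variant is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bold_sim import BoldDataset, _epoch_boxcar
from .glm import DesignMatrix, build_design_matrix, double_gamma_hrf, fit_glm
from .synthetic import ExperimentDesign


@dataclass
class PpiRegressors:
    seed: np.ndarray  # mean timecourse over seed voxels
    boxcar: np.ndarray  # mean-centred psychological variable
    interaction: np.ndarray  # seed * centred boxcar, elementwise
    epoch_kind: str  # "stimulus" | "iti"


def task_boxcar(
    design: ExperimentDesign, epoch_kind: str, run_lengths: list[int]
) -> np.ndarray:
    """0/1 boxcar over the requested epochs, sampled on the TR grid."""
    run_ids = sorted(design.trials["run"].unique())
    parts = []
    for r, n_scans in zip(run_ids, run_lengths):
        epochs = (
            design.stimulus_epochs(r) if epoch_kind == "stimulus"
            else design.iti_epochs(r)
        )
        parts.append(_epoch_boxcar(epochs, n_scans, design.tr))
    return np.concatenate(parts)


def build_ppi_regressor(
    bold: BoldDataset,
    seed_mask: np.ndarray,
    design: ExperimentDesign,
    epoch_kind: str = "stimulus",
    deconvolve: bool = False,
) -> PpiRegressors:
    """Seed timecourse, centred psychological boxcar, and their product.

    With ``deconvolve`` the seed is deconvolved with the canonical HRF
    (Wiener filter), the product formed at the neural level, and the result
    re-convolved — the gPPI-style variant.  Default is the signal-level
    product.
    """
    if epoch_kind not in ("stimulus", "iti"):
        raise ValueError(f"unknown epoch_kind {epoch_kind!r}")
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    seed = bold.data[seed_mask].mean(axis=0)
    box = task_boxcar(design, epoch_kind, bold.run_lengths)
    centred = box - box.mean()
    if not deconvolve:
        interaction = seed * centred
    else:
        interaction = _deconvolved_interaction(seed, centred, bold.tr)
    return PpiRegressors(seed, centred, interaction, epoch_kind)


def _deconvolved_interaction(seed, centred_box, tr):
    n = seed.size
    t = np.arange(0, 32.0, tr)
    h = double_gamma_hrf(t)
    H = np.fft.rfft(h, n)
    S = np.fft.rfft(seed - seed.mean())
    lam = 0.1 * np.abs(H).max() ** 2
    neural = np.fft.irfft(S * np.conj(H) / (np.abs(H) ** 2 + lam), n)
    prod = neural * centred_box
    return np.convolve(prod, h)[:n]


def ppi_map(
    bold: BoldDataset,
    ppi: PpiRegressors,
    design: ExperimentDesign,
    modulators: pd.DataFrame,
    nuisance: pd.DataFrame | None = None,
    alpha: float = 0.001,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel t map of the PPI interaction term.

    The base design uses boxcar-modulated feature and rating regressors,
    plus the seed and psychological main effects and nuisance columns; the
    interaction is tested one-sided (positive tail) at ``alpha``
    uncorrected.  Returns (t values, significance flags).
    """
    base = build_design_matrix(design, modulators=modulators, nuisance=nuisance,
                               mode="epoch_boxcar")
    names = base.names + ["ppi_seed", "ppi_psych", "ppi_interaction"]
    X = np.column_stack([base.matrix, ppi.seed, ppi.boxcar, ppi.interaction])
    dm = DesignMatrix(X, names, base.tr, base.run_lengths, base.task_columns)
    Xn = X / np.maximum(np.linalg.norm(X, axis=0), 1e-300)
    cond = np.linalg.cond(Xn)
    if cond > 1e8:
        import warnings

        warnings.warn("PPI design is ill-conditioned; interpret t-values with care",
                      stacklevel=2)
    fit = fit_glm(bold.data, dm)
    j = names.index("ppi_interaction")
    se = np.sqrt(np.maximum(fit.sigma2 * fit.xtx_inv[j, j], 1e-300))
    t = fit.betas[j] / se
    p = stats.t.sf(t, fit.dof)  # positive tail
    return t, p < alpha


@dataclass
class OverlapReport:
    table: pd.DataFrame  # per ROI: n_feature, n_overlap, fraction
    epoch_kind: str


def feature_ppi_overlap(
    feature_significant: np.ndarray,
    ppi_significant: np.ndarray,
    roi_labels: np.ndarray,
    roi_order: list[str] | None = None,
    epoch_kind: str = "stimulus",
) -> OverlapReport:
    """Fraction of feature-encoding voxels that are also PPI-positive, per ROI.

    ROIs without any feature-significant voxel get an undefined (NaN)
    fraction.
    """
    feature_significant = np.asarray(feature_significant, dtype=bool)
    ppi_significant = np.asarray(ppi_significant, dtype=bool)
    rois = roi_order or list(dict.fromkeys(roi_labels))
    rows = []
    for roi in rois:
        vox = roi_labels == roi
        n_feat = int((feature_significant & vox).sum())
        n_both = int((feature_significant & ppi_significant & vox).sum())
        rows.append(
            {
                "roi": roi,
                "n_feature": n_feat,
                "n_overlap": n_both,
                "fraction": (n_both / n_feat) if n_feat > 0 else np.nan,
            }
        )
    return OverlapReport(pd.DataFrame(rows).set_index("roi"), epoch_kind)
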