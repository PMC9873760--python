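"""fMRI GLM machinery: HRF, design matrices, OLS fits, trial betas, F-tests.

Design matrices are built per run (convolution never crosses a run
boundary) and stacked.  Parametric modulators are mean-centred before
convolution and no serial orthogonalisation is applied between them, so
each regressor's statistic reflects its partial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats


# ---------------------------------------------------------------------------
# Canonical double-gamma HRF


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
    dispersion: float = 1.0,
    u_dispersion: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at times ``t`` (seconds).

    Peak at 6 s, undershoot at 16 s, peak:undershoot ratio 6; normalised to
    unit peak.  Matches the canonical kernel used by standard fMRI packages.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gpdf(x, shape, scale):
        return (
            x ** (shape - 1)
            * np.exp(-x / scale)
            / (special.gamma(shape) * scale**shape)
        )

    h = gpdf(tp, peak_delay / dispersion, dispersion) - gpdf(
        tp, undershoot_delay / u_dispersion, u_dispersion
    ) / ratio
    out[pos] = h
    m = out.max()
    if m > 0:
        out = out / m
    return out


# ---------------------------------------------------------------------------
# Design matrices


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (timepoints, regressors)
    names: list[str]
    tr: float
    run_lengths: list[int]
    task_columns: list[str] = field(default_factory=list)

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def _convolve_run(
    onsets: np.ndarray,
    durations: np.ndarray,
    amplitudes: np.ndarray,
    n_scans: int,
    tr: float,
    oversample: int = 16,
) -> np.ndarray:
    """HRF-convolved regressor sampled on the TR grid of one run."""
    dt = tr / oversample
    n_fine = n_scans * oversample
    fine = np.zeros(n_fine)
    for o, d, a in zip(onsets, durations, amplitudes):
        i0 = int(round(o / dt))
        if d <= 0:  # stick
            if 0 <= i0 < n_fine:
                fine[i0] += a
        else:
            i1 = int(round((o + d) / dt))
            fine[max(i0, 0) : min(i1, n_fine)] += a
    t_hrf = np.arange(0, 32.0, dt)
    kernel = double_gamma_hrf(t_hrf)
    conv = np.convolve(fine, kernel)[:n_fine]
    return conv[::oversample]


def build_design_matrix(
    design,
    modulators: pd.DataFrame | None = None,
    nuisance: pd.DataFrame | None = None,
    mode: str = "onset_stick",
    include_task_sticks: bool = True,
    add_run_intercepts: bool = True,
    rank_check: bool = True,
) -> DesignMatrix:
    """Assemble a stacked multi-run design matrix.

    ``design`` is an :class:`~artvalue.synthetic.ExperimentDesign`.
    ``modulators`` holds one column per parametric regressor, one row per
    trial (aligned with the design's trial order); each is mean-centred
    before convolution.  ``mode`` selects stick-at-onset or 3-s boxcar
    parametric encoding.  Unconvolved nuisance columns (one row per
    timepoint across all runs) are appended as supplied.  Raises on a
    rank-deficient result, naming the collinear columns.
    """
    if mode not in ("onset_stick", "epoch_boxcar"):
        raise ValueError(f"unknown mode {mode!r}")
    trials = design.trials
    tr = design.tr
    run_ids = sorted(trials["run"].unique())
    run_lengths = [design.run_n_scans(r) for r in run_ids]

    columns: dict[str, np.ndarray] = {}

    def convolved(colname, onset_col, dur, amplitudes=None):
        parts = []
        for r, n_scans in zip(run_ids, run_lengths):
            sub = trials[trials["run"] == r]
            amp = (
                np.ones(len(sub))
                if amplitudes is None
                else np.asarray(amplitudes.loc[sub.index], dtype=float)
            )
            durs = np.full(len(sub), dur) if np.isscalar(dur) else dur.loc[sub.index].values
            parts.append(
                _convolve_run(sub[onset_col].values, durs, amp, n_scans, tr)
            )
        columns[colname] = np.concatenate(parts)

    task_cols: list[str] = []
    if modulators is not None:
        if len(modulators) != len(trials):
            raise ValueError("modulator rows must align to trials")
        dur = 0.0 if mode == "onset_stick" else trials["stim_duration"]
        for name in modulators.columns:
            centred = modulators[name] - modulators[name].mean()
            convolved(name, "stim_onset", dur, centred)
            task_cols.append(name)

    if include_task_sticks:
        convolved("stim_onset_stick", "stim_onset", 0.0)
        convolved("decision_onset_stick", "decision_onset", 0.0)
        convolved("action_onset_stick", "action_onset", 0.0)
        convolved("feedback_onset_stick", "feedback_onset", 0.0)

    n_total = sum(run_lengths)
    if add_run_intercepts:
        off = 0
        for r, n_scans in zip(run_ids, run_lengths):
            col = np.zeros(n_total)
            col[off : off + n_scans] = 1.0
            columns[f"run_{r}_intercept"] = col
            off += n_scans
    if nuisance is not None:
        if len(nuisance) != n_total:
            raise ValueError("nuisance rows must match total timepoints")
        for name in nuisance.columns:
            columns[f"nuis_{name}"] = np.asarray(nuisance[name], dtype=float)

    names = list(columns)
    X = np.column_stack([columns[n] for n in names])
    if rank_check:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            bad = _collinear_columns(X, names)
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(X, names, tr, run_lengths, task_cols)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    thresh = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [n for n, d in zip(names, diag) if d < max(thresh, 1e-10)]


# ---------------------------------------------------------------------------
# OLS fit and tests


@dataclass
class GlmFit:
    design: DesignMatrix
    betas: np.ndarray  # (regressors, voxels)
    sigma2: np.ndarray  # (voxels,)
    dof: int
    xtx_inv: np.ndarray

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.design.names.index(name)]


def fit_glm(bold: np.ndarray, design: DesignMatrix) -> GlmFit:
    """OLS fit of every voxel's timecourse on the design matrix.

    ``bold`` is (voxels, timepoints).
    """
    X = design.matrix
    Y = np.asarray(bold, dtype=float).T  # (T, V)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("BOLD timepoints do not match the design")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    return GlmFit(design, beta, sigma2, dof, xtx_inv)


def t_statistic(fit: GlmFit, name: str) -> np.ndarray:
    """Per-voxel t statistic for one regressor."""
    j = fit.design.names.index(name)
    se = np.sqrt(np.maximum(fit.sigma2 * fit.xtx_inv[j, j], 1e-300))
    return fit.betas[j] / se


def group_f_test(
    fit: GlmFit, group: list[str], alpha: float = 0.001
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partial F test over a named group of regressors, per voxel.

    Uses the diagonal contrast over the group's columns:
    F = (b' M^{-1} b / q) / sigma^2 with M the group block of (X'X)^{-1}.
    Returns (F values, p values, significance at ``alpha`` uncorrected).
    """
    missing = [g for g in group if g not in fit.design.names]
    if missing:
        raise KeyError(f"regressors not in design: {missing}")
    idx = [fit.design.names.index(g) for g in group]
    q = len(idx)
    B = fit.betas[idx]  # (q, V)
    M = fit.xtx_inv[np.ix_(idx, idx)]
    Minv = np.linalg.pinv(M)
    quad = np.einsum("qv,qr,rv->v", B, Minv, B)
    F = quad / q / np.maximum(fit.sigma2, 1e-300)
    p = stats.f.sf(F, q, fit.dof)
    return F, p, p < alpha


# ---------------------------------------------------------------------------
# Per-trial beta estimation


def estimate_trial_betas(
    bold: np.ndarray,
    design,
    nuisance: pd.DataFrame | None = None,
) -> np.ndarray:
    """Betas of one stick regressor per trial at stimulus onset.

    A single GLM holds every trial's onset regressor together with the
    decision/action/feedback onset sticks, run intercepts, and any supplied
    nuisance columns.  Returns (trials, voxels) in the design's trial order.
    """
    trials = design.trials
    tr = design.tr
    run_ids = sorted(trials["run"].unique())
    run_lengths = [design.run_n_scans(r) for r in run_ids]
    n_total = sum(run_lengths)
    n_trials = len(trials)
    if n_trials + 4 > n_total:
        raise ValueError(
            "more regressors than timepoints; estimate per run instead"
        )

    cols = []
    names = []
    offsets = dict(zip(run_ids, np.cumsum([0] + run_lengths[:-1])))
    lengths = dict(zip(run_ids, run_lengths))
    for t_idx, row in trials.iterrows():
        r = row["run"]
        reg = np.zeros(n_total)
        conv = _convolve_run(
            np.array([row["stim_onset"]]), np.array([0.0]), np.array([1.0]),
            lengths[r], tr,
        )
        reg[offsets[r] : offsets[r] + lengths[r]] = conv
        cols.append(reg)
        names.append(f"trial_{t_idx}")

    aux = build_design_matrix(
        design, modulators=None, nuisance=nuisance, include_task_sticks=True,
        rank_check=False,
    )
    # drop the plain stimulus-onset stick: it is the sum of the trial sticks
    keep = [i for i, n in enumerate(aux.names) if n != "stim_onset_stick"]
    X = np.column_stack(cols + [aux.matrix[:, i] for i in keep])
    Y = np.asarray(bold, dtype=float).T
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    return beta[:n_trials]
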