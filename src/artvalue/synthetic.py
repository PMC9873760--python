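"""Synthetic study generator: stimuli, annotations, ratings and designs.

Everything downstream of real data collection is emulated here with planted,
recoverable structure: procedural stimulus images with known segment layout,
high-level annotations as noisy linear mixtures of low-level features,
ratings from the linear feature-summation rule plus noise discretised to the
0-3 scale, and the trial timing of the rating task (3 s stimulus, 3 s
decision window, 0.5 s feedback, 2-9 s jittered ITIs, 50 trials per run,
20 runs, TR 1.12 s).  All generators are deterministic given their seed and
record their parameters in a manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterImage

HIGH_LEVEL_NAMES = ["concreteness", "dynamics", "temperature", "valence",
                    "presence_person"]


# ---------------------------------------------------------------------------
# Stimulus images


@dataclass
class StimulusSet:
    images: list[RasterImage]
    truth: pd.DataFrame  # intended feature values per image
    manifest: dict


def make_stimulus_images(
    n: int,
    seed: int = 0,
    size: tuple[int, int] = (64, 64),
    n_segments_range: tuple[int, int] = (2, 5),
    p_symmetric: float = 0.25,
    blur_sigmas: tuple[float, ...] = (0.0, 0.0, 1.0, 2.0),
    border_margin: int | None = None,
) -> StimulusSet:
    """Procedural stimuli: solid-colour bands/rectangles over a background.

    Each image is a background colour with 1-4 solid shapes on top; an image
    may be mirrored about its vertical axis (exact horizontal symmetry) and
    may be Gaussian-blurred.  Shapes are kept ``border_margin`` pixels away
    from the image border (default: an eighth of the smaller edge) so the
    borders stay uniform — this keeps the discrete spectrum free of
    wrap-around leakage, which would otherwise dominate the blur feature.
    The constructor's intended values for checkable features
    (largest-segment area fraction, symmetry class, blur sigma) are
    returned alongside the pixels.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    h, w = size
    margin = border_margin if border_margin is not None else max(2, min(h, w) // 8)
    images = []
    rows = []
    for i in range(n):
        n_seg = int(rng.integers(n_segments_range[0], n_segments_range[1] + 1))
        bg = rng.uniform(0.05, 0.95, size=3)
        img = np.broadcast_to(bg, (h, w, 3)).copy()
        symmetric = bool(rng.random() < p_symmetric)
        # symmetric images are built by mirroring the left half, so their
        # shapes are drawn on the left to survive the mirror
        x_hi = w // 2 if symmetric else w - margin
        for _ in range(n_seg - 1):
            colour = rng.uniform(0.0, 1.0, size=3)
            # keep shapes well separated in colour from the background
            while np.abs(colour - bg).max() < 0.25:
                colour = rng.uniform(0.0, 1.0, size=3)
            sh = int(rng.integers(h // 8, h // 2))
            sw = int(rng.integers(w // 8, w // 2))
            y0 = int(rng.integers(margin, max(margin + 1, h - margin - sh)))
            x0 = int(rng.integers(margin, max(margin + 1, x_hi - sw)))
            img[y0 : min(y0 + sh, h - margin), x0 : min(x0 + sw, x_hi)] = colour
        if symmetric:
            img[:, w - w // 2 :] = img[:, : w // 2][:, ::-1]
        sigma = float(rng.choice(blur_sigmas))
        if sigma > 0:
            # periodic (wrap) smoothing: the discrete spectrum is then
            # attenuated exactly as the Gaussian-blur model assumes
            img = gaussian_filter(img, sigma=(sigma, sigma, 0.0), mode="wrap")
        img = np.clip(img, 0.0, 1.0)
        # intended largest-segment fraction: modal colour's share
        flat = np.round(img.reshape(-1, 3), 4)
        _, counts = np.unique(flat, axis=0, return_counts=True)
        rows.append(
            {
                "stimulus": i,
                "largest_segment_fraction": counts.max() / flat.shape[0],
                "symmetric": symmetric,
                "blur_sigma": sigma,
                "n_shapes": n_seg,
            }
        )
        images.append(RasterImage(img))
    truth = pd.DataFrame(rows).set_index("stimulus")
    manifest = {
        "generator": "make_stimulus_images",
        "n": n, "seed": seed, "size": list(size),
        "n_segments_range": list(n_segments_range),
        "p_symmetric": p_symmetric, "blur_sigmas": list(blur_sigmas),
        "border_margin": margin,
    }
    return StimulusSet(images, truth, manifest)


# ---------------------------------------------------------------------------
# High-level annotations


def make_annotations(
    low_level: pd.DataFrame,
    mixing: np.ndarray | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """High-level attributes as noisy linear mixtures of low-level features.

    Each of concreteness/dynamics/temperature/valence is a random linear
    combination of the (z-scored) low-level columns plus independent
    Gaussian noise; presence-of-a-person is a thresholded binary built the
    same way.  With ``noise_sd=0`` the continuous columns are exactly linear
    in the low-level features.
    """
    rng = np.random.default_rng(seed)
    X = low_level.values.astype(float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    k = Z.shape[1]
    if mixing is None:
        mixing = rng.standard_normal((k, len(HIGH_LEVEL_NAMES))) / np.sqrt(k)
    base = Z @ mixing
    noisy = base + noise_sd * rng.standard_normal(base.shape)
    out = pd.DataFrame(noisy, index=low_level.index, columns=HIGH_LEVEL_NAMES)
    out["presence_person"] = (noisy[:, -1] > np.median(noisy[:, -1])).astype(float)
    manifest = {"generator": "make_annotations", "noise_sd": noise_sd, "seed": seed}
    return out, manifest


# ---------------------------------------------------------------------------
# Ratings


@dataclass
class RatingDataset:
    ratings: pd.DataFrame  # participants x stimuli, integers 0-3
    continuous: pd.DataFrame  # ground-truth continuous values
    weights: pd.DataFrame  # planted weights, participants x features
    manifest: dict


def make_ratings(
    features: pd.DataFrame,
    weights: pd.DataFrame | None = None,
    n_participants: int = 6,
    noise_sd: float = 1.0,
    sparsity: float = 0.0,
    seed: int = 0,
) -> RatingDataset:
    """Ratings from the linear feature-summation rule plus noise.

    Continuous value = z-scored features @ w* + Gaussian noise, discretised
    to {0,1,2,3} by that participant's population quartiles (balanced
    classes).  With ``weights=None`` each participant receives random unit
    weights; ``sparsity`` zeroes that fraction of them.  The continuous
    values and planted weights are retained for recovery tests.
    """
    rng = np.random.default_rng(seed)
    X = features.values.astype(float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    n, k = Z.shape
    if weights is None:
        W = rng.standard_normal((n_participants, k))
        if sparsity > 0:
            for s in range(n_participants):
                off = rng.choice(k, size=int(round(sparsity * k)), replace=False)
                W[s, off] = 0.0
        norms = np.linalg.norm(W, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        W = W / norms * np.sqrt(k)
        weights = pd.DataFrame(W, columns=features.columns)
    W = weights.values
    cont = Z @ W.T  # (stimuli, participants)
    signal_sd = cont.std(axis=0)
    signal_sd[signal_sd == 0] = 1.0
    noisy = cont + noise_sd * signal_sd[None, :] * rng.standard_normal(cont.shape)
    discrete = np.empty_like(noisy, dtype=int)
    for s in range(noisy.shape[1]):
        q = np.quantile(noisy[:, s], [0.25, 0.5, 0.75])
        discrete[:, s] = np.digitize(noisy[:, s], q)
    ratings = pd.DataFrame(discrete.T, columns=features.index)
    ratings.index.name = "participant"
    continuous = pd.DataFrame(noisy.T, columns=features.index)
    manifest = {
        "generator": "make_ratings", "n_participants": int(W.shape[0]),
        "noise_sd": noise_sd, "sparsity": sparsity, "seed": seed,
    }
    return RatingDataset(ratings, continuous, weights, manifest)


# ---------------------------------------------------------------------------
# Experimental design


@dataclass
class ExperimentDesign:
    trials: pd.DataFrame
    tr: float = 1.12
    tail_s: float = 8.0

    def run_n_scans(self, run: int) -> int:
        sub = self.trials[self.trials["run"] == run]
        end = (sub["feedback_onset"] + sub["feedback_duration"] + sub["iti"]).max()
        return int(np.ceil((end + self.tail_s) / self.tr))

    @property
    def n_scans_total(self) -> int:
        return sum(self.run_n_scans(r) for r in sorted(self.trials["run"].unique()))

    def stimulus_epochs(self, run: int) -> np.ndarray:
        sub = self.trials[self.trials["run"] == run]
        return np.column_stack([sub["stim_onset"], sub["stim_onset"] + sub["stim_duration"]])

    def iti_epochs(self, run: int) -> np.ndarray:
        sub = self.trials[self.trials["run"] == run]
        start = sub["feedback_onset"] + sub["feedback_duration"]
        return np.column_stack([start, start + sub["iti"]])


def make_design(
    runs: int = 20,
    trials_per_run: int = 50,
    seed: int = 0,
    tr: float = 1.12,
    stim_duration: float = 3.0,
    decision_window: float = 3.0,
    feedback_duration: float = 0.5,
    iti_range: tuple[float, float] = (2.0, 9.0),
    lead_in_s: float = 4.0,
) -> tuple[ExperimentDesign, dict]:
    """Trial timing: stimulus, decision, action, feedback epochs and ITIs.

    Onsets are run-relative.  Every trial shows a unique stimulus; the
    action (button press) falls inside the decision window at a simulated
    reaction time.
    """
    rng = np.random.default_rng(seed)
    rows = []
    stim_id = 0
    for r in range(runs):
        t = lead_in_s
        for k in range(trials_per_run):
            iti = float(rng.uniform(*iti_range))
            rt = float(rng.uniform(0.3, decision_window - 0.3))
            decision_onset = t + stim_duration
            rows.append(
                {
                    "run": r, "trial": k, "stimulus": stim_id,
                    "stim_onset": t, "stim_duration": stim_duration,
                    "decision_onset": decision_onset,
                    "action_onset": decision_onset + rt,
                    "feedback_onset": decision_onset + decision_window,
                    "feedback_duration": feedback_duration,
                    "iti": iti,
                }
            )
            t = decision_onset + decision_window + feedback_duration + iti
            stim_id += 1
    trials = pd.DataFrame(rows)
    manifest = {
        "generator": "make_design", "runs": runs,
        "trials_per_run": trials_per_run, "seed": seed, "tr": tr,
        "stim_duration": stim_duration, "decision_window": decision_window,
        "feedback_duration": feedback_duration, "iti_range": list(iti_range),
        "lead_in_s": lead_in_s,
    }
    return ExperimentDesign(trials, tr=tr), manifest


def write_events_tsv(design: ExperimentDesign, directory) -> None:
    """BIDS-style per-run events tables."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for r in sorted(design.trials["run"].unique()):
        sub = design.trials[design.trials["run"] == r]
        ev = pd.DataFrame(
            {
                "onset": sub["stim_onset"],
                "duration": sub["stim_duration"],
                "trial_type": "stimulus",
                "stimulus": sub["stimulus"],
            }
        )
        ev.to_csv(directory / f"run-{r:02d}_events.tsv", sep="\t", index=False)


def save_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
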