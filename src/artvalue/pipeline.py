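"""End-to-end synthetic study runs.

Each function stages one analysis of the pipeline at desk scale: generate
synthetic inputs with planted structure, run the estimator, and report what
it recovered.  The numbered scripts under ``analysis/`` and the acceptance
script are thin wrappers over these functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bold_sim import RoiSpec, make_bold
from .catalog import SHARED_FEATURE_NAMES, build_catalog
from .encoding import feature_glm, group_f_maps, roi_proportion_profile
from .extract import extract_feature_table
from .glm import build_design_matrix, fit_glm, group_f_test
from .lfs import fit_ridge_cv, permutation_test
from .ppi import build_ppi_regressor, feature_ppi_overlap, ppi_map
from .probe_decode import (
    classify_feature_level,
    decode_feature_from_layer,
    layer_activations,
)
from .probe_net import RatingNet, RatingNetConfig, preprocess_images
from .selection import group_lasso_cv
from .synthetic import (
    make_annotations,
    make_design,
    make_ratings,
    make_stimulus_images,
)

FEATURE_ROI_NAMES = ["V1", "V2", "V4", "LO", "PHC"]
FEATURE_ROI_GRADIENT = [0.1, 0.3, 0.5, 0.7, 0.9]

#: reference probe-network configuration for the layerwise decoding analyses
PROBE_CONFIG = RatingNetConfig(
    input_size=16,
    conv_channels=(8, 8, 6, 6, 8, 8, 10, 10),
    pool_after=(1, 3, 5),
    fc_sizes=(24, 12),
    batch_size=20,
)


def extract_stimulus_features(
    n_images: int = 120,
    seed: int = 0,
    image_size: tuple[int, int] = (48, 48),
) -> tuple[pd.DataFrame, dict]:
    """Generate procedural stimuli and extract the full 83-feature table."""
    catalog = build_catalog()
    stim = make_stimulus_images(n_images, seed=seed, size=image_size)
    low_probe = pd.DataFrame(
        {
            "frac": stim.truth["largest_segment_fraction"],
            "blur": stim.truth["blur_sigma"],
            "sym": stim.truth["symmetric"].astype(float),
        }
    )
    annotations, _ = make_annotations(low_probe, noise_sd=0.3, seed=seed + 1)
    table = extract_feature_table(stim.images, catalog, annotations, seed=seed)
    manifest = {"n_images": n_images, "seed": seed, "image_size": list(image_size)}
    return table, manifest


def behavioural_fit(
    features: pd.DataFrame,
    n_participants: int = 6,
    noise_sd: float = 1.0,
    n_folds: int = 20,
    n_perm: int = 500,
    seed: int = 0,
) -> dict:
    """Fit the value model per participant on synthetic ratings.

    Ratings are generated from the shared-set features by the linear
    summation rule, discretised to 0-3; the model is fit with 20-fold
    cross-validated ridge and its pooled accuracy tested against a
    permutation null for the first participant.
    """
    shared = features[[c for c in SHARED_FEATURE_NAMES if c in features.columns]]
    shared = shared.loc[:, shared.std() > 0]
    ds = make_ratings(shared, n_participants=n_participants, noise_sd=noise_sd,
                      seed=seed + 2)
    grid = np.logspace(-2, 3, 8)
    accs, recovery = [], []
    for s in range(n_participants):
        wv, cv = fit_ridge_cv(
            shared.values, ds.ratings.iloc[s].values, n_folds=n_folds,
            penalty_grid=grid, seed=seed, feature_names=shared.columns,
        )
        accs.append(cv.accuracy)
        west = wv.as_array([c for c in shared.columns if c in wv.weights])
        wtrue = ds.weights.iloc[s][[c for c in shared.columns if c in wv.weights]]
        recovery.append(float(np.corrcoef(west, wtrue)[0, 1]))
    p, null = permutation_test(
        shared.values, ds.ratings.iloc[0].values, observed_accuracy=accs[0],
        n_perm=n_perm, n_folds=5, penalty_grid=np.array([1.0]), seed=seed,
    )
    return {
        "accuracy_mean": float(np.mean(accs)),
        "accuracy_per_participant": [float(a) for a in accs],
        "weight_recovery_r_mean": float(np.mean(recovery)),
        "permutation_p": float(p),
        "chance_level": float(null.mean()),
        "n_stimuli": int(shared.shape[0]),
    }


def support_recovery(
    n_seeds: int = 10,
    n_stimuli: int = 150,
    n_features: int = 10,
    n_participants: int = 4,
    support=(0, 3, 7),
    noise_sd: float = 0.5,
    seed: int = 0,
) -> dict:
    """Planted-support recovery rate of the group-lasso selection."""
    hits = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + 31 * k)
        X = rng.standard_normal((n_stimuli, n_features))
        ys = []
        for _ in range(n_participants):
            w = np.zeros(n_features)
            w[list(support)] = rng.uniform(1, 2, len(support)) * rng.choice(
                [-1, 1], len(support)
            )
            ys.append(X @ w + noise_sd * rng.standard_normal(n_stimuli))
        fit, _, _ = group_lasso_cv([X] * n_participants, ys, n_folds=5,
                                   n_lambdas=20, seed=seed + k)
        active = set(np.nonzero(fit.group_norms() > 1e-8)[0].tolist())
        hits += active == set(support)
    return {"rate": hits / n_seeds, "n_seeds": n_seeds}


def _session_rois(n_voxels: int) -> list[RoiSpec]:
    rois = [
        RoiSpec(n, "feature", n_voxels, g)
        for n, g in zip(FEATURE_ROI_NAMES, FEATURE_ROI_GRADIENT)
    ]
    rois += [
        RoiSpec("PPC", "integrator", n_voxels, 0.5, coupled=True),
        RoiSpec("lPFC", "integrator", n_voxels, 0.5, coupled=True),
        RoiSpec("mPFC", "value", n_voxels, 0.0, coupled=True),
    ]
    return rois


def simulate_session(
    seed: int,
    runs: int = 4,
    trials_per_run: int = 25,
    n_voxels: int = 20,
    n_low: int = 5,
    n_high: int = 3,
    coupling_strength: float = 0.8,
    signal_scale: float = 1.0,
):
    """One synthetic participant: design, features, ratings, BOLD."""
    design, _ = make_design(runs=runs, trials_per_run=trials_per_run, seed=seed)
    rng = np.random.default_rng(seed + 10_000)
    n_tr = len(design.trials)
    cols = [f"low{i}" for i in range(n_low)] + [f"high{i}" for i in range(n_high)]
    feats = pd.DataFrame(rng.standard_normal((n_tr, n_low + n_high)), columns=cols)
    levels = {c: ("low" if c.startswith("low") else "high") for c in cols}
    ratings = feats.values @ rng.standard_normal(n_low + n_high)
    ratings = ratings + ratings.std() * rng.standard_normal(n_tr)
    bold = make_bold(
        design, feats, levels, ratings, rois=_session_rois(n_voxels),
        coupling_strength=coupling_strength, signal_scale=signal_scale,
        seed=seed + 20_000,
    )
    return design, feats, levels, ratings, bold


def encoding_hierarchy(seed: int = 0, n_seeds: int = 10, **session_kwargs) -> dict:
    """Hierarchy recovery: proportion profiles over the planted ROI gradient."""
    indices = []
    profile = None
    for k in range(n_seeds):
        design, feats, levels, ratings, bold = simulate_session(
            seed + 101 * k, **session_kwargs
        )
        fit = feature_glm(bold, design, feats, nuisance=bold.nuisance)
        groups = {
            "low": [c for c in feats if levels[c] == "low"],
            "high": [c for c in feats if levels[c] == "high"],
        }
        maps = group_f_maps(fit, groups, alpha=0.001)
        prof = roi_proportion_profile(maps, bold.roi_labels, FEATURE_ROI_NAMES)
        indices.append(prof.hierarchy_index)
        if profile is None:
            profile = prof.proportions
    return {
        "hierarchy_index_mean": float(np.mean(indices)),
        "hierarchy_indices": [float(i) for i in indices],
        "recovery_rate": float(np.mean([i >= 0.8 for i in indices])),
        "example_profile": profile,
    }


def f_test_calibration(seed: int = 0, n_voxels: int = 5000, alpha: float = 0.001) -> dict:
    """Null rejection rate of the group F test on pure-noise voxels."""
    design, _ = make_design(runs=2, trials_per_run=20, seed=seed)
    rng = np.random.default_rng(seed + 1)
    mods = pd.DataFrame(
        rng.standard_normal((len(design.trials), 3)), columns=["a", "b", "c"]
    )
    dm = build_design_matrix(design, mods)
    Y = rng.standard_normal((n_voxels, dm.n_timepoints))
    fit = fit_glm(Y, dm)
    _, _, sig = group_f_test(fit, ["a", "b", "c"], alpha=alpha)
    return {"rejection_rate": float(sig.mean()), "alpha": alpha, "n_voxels": n_voxels}


def ppi_overlap_analysis(seed: int = 0, coupling_strength: float = 0.8,
                         **session_kwargs) -> dict:
    """Stimulus- vs ITI-epoch PPI overlap with feature-encoding voxels."""
    design, feats, levels, ratings, bold = simulate_session(
        seed, coupling_strength=coupling_strength, **session_kwargs
    )
    mods = feats.copy()
    mods["rating"] = ratings
    fmap = group_f_maps(
        feature_glm(bold, design, feats, nuisance=bold.nuisance),
        {"any": list(feats.columns)}, alpha=0.001,
    )
    feat_sig = fmap.significant["any"]
    order = FEATURE_ROI_NAMES + ["PPC", "lPFC"]
    out = {}
    for kind in ("stimulus", "iti"):
        ppi = build_ppi_regressor(bold, bold.roi_mask("mPFC"), design, kind)
        _, psig = ppi_map(bold, ppi, design, mods, nuisance=bold.nuisance)
        out[kind] = feature_ppi_overlap(feat_sig, psig, bold.roi_labels, order,
                                        kind).table
    stim = out["stimulus"]["fraction"]
    iti = out["iti"]["fraction"]
    return {
        "stimulus_table": out["stimulus"],
        "iti_table": out["iti"],
        "overlap_coupled_stimulus": float(np.nanmean([stim["PPC"], stim["lPFC"]])),
        "overlap_visual_stimulus": float(
            np.nanmean([stim[r] for r in FEATURE_ROI_NAMES])
        ),
        "overlap_coupled_iti": float(np.nanmean([iti["PPC"], iti["lPFC"]])),
    }


def probe_classification(
    seed: int = 0,
    n_seeds: int = 5,
    n_images: int = 160,
    epochs: int = 80,
    lr: float = 0.02,
    n_folds: int = 10,
    n_perm: int = 10000,
    trained: bool = True,
) -> dict:
    """Planted shallow/deep feature classification by decoding slope.

    A small rating network is trained on procedural stimuli whose ratings
    follow layout properties (largest-segment size, symmetry).  The shallow
    probe feature is a pixel statistic irrelevant to the rating (mean blue
    channel); the deep probe feature is a threshold of the trained network's
    own readout.  Training occasionally sticks in a poor optimum; when the
    training-set correlation stays below ``min_train_r`` the network is
    re-initialised (up to four fresh inits - a training-side
    criterion only).  With ``trained=False`` activations come from random
    untrained weights (the control in which the deep feature should lose
    its high-level signature).
    """
    shallow_ok = deep_ok = 0
    records = []
    min_train_r, max_restarts = 0.75, 4
    for k in range(n_seeds):
        s = seed + 17 * k
        rng = np.random.default_rng(s)
        stim = make_stimulus_images(n_images, seed=s, size=(16, 16))
        X = preprocess_images(stim.images, 16)
        y_cont = (
            stim.truth["largest_segment_fraction"].values
            + 1.5 * stim.truth["symmetric"].values
            + 0.2 * rng.standard_normal(n_images)
        )
        y = np.clip(3 * (y_cont - y_cont.min()) / (np.ptp(y_cont) + 1e-9), 0, 3)
        net = RatingNet(PROBE_CONFIG, seed=s)
        trained_net, best_r = None, -2.0
        for t in range(max_restarts):
            cand = RatingNet(PROBE_CONFIG, seed=s + 1_000_003 * t)
            cand.train(X, y, epochs=epochs, seed=s + 1_000_003 * t, lr=lr)
            pred = cand.predict(X)
            r = float(np.corrcoef(pred, y)[0, 1]) if pred.std() > 0 else -1.0
            if r > best_r:
                trained_net, best_r = cand, r
            if r >= min_train_r:
                break
        probe_net = trained_net if trained else net
        acts = layer_activations(probe_net, X)
        shallow = X[:, 2].mean(axis=(1, 2))
        readout = trained_net.predict(X)
        deep = (readout > np.median(readout)).astype(float)
        s_scores = [
            decode_feature_from_layer(a, shallow, "continuous", n_folds=n_folds,
                                      seed=s)["score"]
            for a in acts
        ]
        d_scores = [
            decode_feature_from_layer(a, deep, "categorical", n_folds=n_folds,
                                      seed=s)["score"]
            for a in acts
        ]
        cs = classify_feature_level(s_scores, n_perm=n_perm, seed=s)
        cd = classify_feature_level(d_scores, n_perm=n_perm, seed=s)
        shallow_ok += cs.label == "low"
        deep_ok += cd.label == "high"
        records.append(
            {"seed": s, "shallow": cs.label, "shallow_p": cs.p_value,
             "deep": cd.label, "deep_p": cd.p_value}
        )
    return {
        "shallow_low_rate": shallow_ok / n_seeds,
        "deep_high_rate": deep_ok / n_seeds,
        "n_seeds": n_seeds,
        "records": records,
    }
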