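"""Nonlinear interaction features from pairs of value-model features.

Products of z-scored feature pairs, grouped into low x low, high x high and
low x high, each group reduced to a fixed number of principal components
(five by default, matching the count of high-level attributes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class InteractionGroups:
    """Three product-feature matrices with per-column pair provenance."""

    matrices: dict[str, pd.DataFrame]  # keys: low_low, high_high, low_high
    pairs: dict[str, list[tuple[str, str]]]


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=0).replace(0, 1.0)
    return (df - df.mean()) / sd


def build_interaction_groups(
    features: pd.DataFrame, levels: dict[str, str]
) -> InteractionGroups:
    """All unordered within-level and all cross-level pairwise products.

    Inputs are z-scored before multiplication; columns are ordered
    lexicographically by their pair names.  A level with fewer than two
    features yields an empty within-level group (with a warning).
    """
    missing = [c for c in features.columns if c not in levels]
    if missing:
        raise ValueError(f"level tags missing for columns: {missing}")
    z = _zscore(features)
    low = sorted(c for c in features.columns if levels[c] == "low")
    high = sorted(c for c in features.columns if levels[c] == "high")
    for tag, cols in (("low", low), ("high", high)):
        if len(cols) < 2:
            warnings.warn(f"fewer than 2 {tag}-level features; empty group",
                          stacklevel=2)

    def products(pairs):
        cols = {}
        for a, b in pairs:
            cols[f"{a}*{b}"] = z[a] * z[b]
        return pd.DataFrame(cols, index=features.index)

    low_low = sorted(combinations(low, 2))
    high_high = sorted(combinations(high, 2))
    low_high = sorted((a, b) for a in low for b in high)
    return InteractionGroups(
        matrices={
            "low_low": products(low_low),
            "high_high": products(high_high),
            "low_high": products(low_high),
        },
        pairs={"low_low": low_low, "high_high": high_high, "low_high": low_high},
    )


def reduce_groups(
    groups: InteractionGroups, n_pcs: int = 5, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Top principal components of each interaction group.

    Each non-empty group contributes ``n_pcs`` component-score columns
    (z-scored); a group with fewer columns than ``n_pcs`` keeps all its
    components and is flagged with a warning.  Returns the combined score
    table and the per-group loading matrices.
    """
    frames = []
    loadings: dict[str, np.ndarray] = {}
    for key, mat in groups.matrices.items():
        if mat.shape[1] == 0:
            continue
        k = n_pcs
        if mat.shape[1] < n_pcs:
            warnings.warn(
                f"group {key} has {mat.shape[1]} columns < {n_pcs} PCs; keeping all",
                stacklevel=2,
            )
            k = mat.shape[1]
        pca = PCA(n_components=k, random_state=seed)
        scores = pca.fit_transform(mat.values)
        sd = scores.std(axis=0)
        sd[sd == 0] = 1.0
        scores = (scores - scores.mean(axis=0)) / sd
        frames.append(
            pd.DataFrame(scores, index=mat.index,
                         columns=[f"{key}_pc{i + 1}" for i in range(k)])
        )
        loadings[key] = pca.components_
    combined = pd.concat(frames, axis=1) if frames else pd.DataFrame(index=None)
    return combined, loadings
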