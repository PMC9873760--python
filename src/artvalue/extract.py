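"""Assemble full feature vectors for images against a catalog."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog
from .features import compute_global_features, compute_segment_features
from .raster import RasterImage
from .segmentation import segment_image


def extract_features(
    image: RasterImage,
    catalog: FeatureCatalog,
    annotations: Mapping[str, float] | None = None,
    *,
    seed: int = 0,
    kmeans_k: int = 3,
    graph_target: int = 6,
    normalize_coords: bool = True,
) -> dict[str, float]:
    """One value per catalog entry, in catalog order.

    Low-level entries are computed from pixels; high-level entries
    (concreteness, dynamics, temperature, valence, presence_person) are
    copied from ``annotations`` — they are inputs, not computed.  Raises
    ``KeyError`` naming the entry if a high-level annotation is missing.
    Features of an absent segment come back as NaN with a warning.
    """
    annotations = annotations or {}

    backends_needed = {e.backend for e in catalog.entries if e.backend}
    segs = {
        b: segment_image(image, b, seed=seed, k=kmeans_k, target_segments=graph_target)
        for b in backends_needed
    }

    global_vals = compute_global_features(image)
    seg_vals: dict[tuple[str, int], dict[str, float]] = {}
    for b, seg in segs.items():
        for idx in (0, 1):
            seg_vals[(b, idx)] = compute_segment_features(
                image, seg, idx, normalize_coords=normalize_coords
            )

    out: dict[str, float] = {}
    missing_segment = False
    for e in catalog.entries:
        if e.level == "high":
            if e.name not in annotations:
                raise KeyError(f"missing high-level annotation: {e.name!r}")
            out[e.name] = float(annotations[e.name])
        elif e.scope == "global":
            out[e.name] = global_vals[e.name]
        else:
            seg_idx = int(e.scope.split("-")[1]) - 1
            base = e.name.split(f"seg{seg_idx + 1}_", 1)[1]
            val = seg_vals[(e.backend, seg_idx)][base]
            if not np.isfinite(val):
                missing_segment = True
            out[e.name] = val
    if missing_segment:
        warnings.warn("some segment features are NaN (segment absent)", stacklevel=2)
    return out


def extract_feature_table(
    images: Sequence[RasterImage],
    catalog: FeatureCatalog,
    annotations: pd.DataFrame | None = None,
    *,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Feature matrix for a list of images: one row per image, catalog columns.

    ``annotations``, if given, is indexed like ``images`` with one column per
    high-level feature.
    """
    rows = []
    for i, img in enumerate(images):
        ann = None
        if annotations is not None:
            ann = annotations.iloc[i].to_dict()
        rows.append(extract_features(img, catalog, ann, seed=seed, **kwargs))
    return pd.DataFrame(rows, columns=catalog.names)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="stimulus")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="stimulus")
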