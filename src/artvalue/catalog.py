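"""The candidate feature registry and the shared feature set.

The catalog enumerates every candidate feature entering the value model:
whole-image statistics computed alongside the graph-backend segmentation,
per-segment statistics for the two largest segments under the graph, SRM and
k-means backends, extra global statistics (intensity bins, HSV modes, aspect
ratio, entropy), and the five externally annotated high-level attributes.

The assembled registry holds 83 entries: 78 pixel-computable low-level
features plus concreteness, dynamics, temperature, valence and
presence-of-a-person.  Presence-of-a-person is pixel-agnostic but entered
the original candidate pool with the low-level features (79 at the selection
stage) before being reclassified as high-level; the catalog tags it
high-level and records that history in its ``ref`` field.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable

GRAPH_GLOBALS = [
    "global_mean_hue", "global_mean_saturation", "global_mean_value",
    "global_mean_lightness", "global_intensity_mean",
    "global_intensity_contrast", "global_blur", "global_edge_density",
    "global_colorfulness", "global_hue_std", "global_saturation_std",
    "global_value_std",
]
GRAPH_LOCALS = [
    "segment_size", "mean_hue", "mean_saturation", "mean_value",
    "mean_lightness", "mean_r", "com_x", "com_y", "variance", "skew",
    "entropy", "h_symmetry", "v_symmetry",
]
SRM_LOCALS = [
    "segment_size", "mean_hue", "mean_saturation", "mean_value",
    "com_x", "com_y", "variance", "skew", "entropy",
    "h_symmetry", "v_symmetry",
]
KMEANS_LOCALS = ["mean_r", "mean_hue", "mean_saturation", "mean_value"]
EXTRA_GLOBALS = [
    "intensity_bin_1", "intensity_bin_2", "intensity_bin_3",
    "intensity_bin_4", "intensity_bin_5",
    "global_mode_hue", "global_mode_saturation", "global_mode_value",
    "aspect_ratio", "global_entropy",
]
HIGH_LEVEL = ["concreteness", "dynamics", "temperature", "valence", "presence_person"]

#: The 18-feature shared set used throughout the neural analyses: the five
#: high-level attributes plus the 13 low-level features retained by the
#: group-level selection (saturation, blur, largest-segment mass centre and
#: second-segment skewness under the graph backend, SRM largest-segment size /
#: hue / value / mass variance, global and second-segment entropy, and the two
#: darkest intensity bins).
SHARED_FEATURE_NAMES = [
    "concreteness",
    "dynamics",
    "temperature",
    "valence",
    "global_mean_saturation",
    "global_blur",
    "graph_seg1_com_x",
    "graph_seg1_com_y",
    "graph_seg2_skew",
    "srm_seg1_segment_size",
    "srm_seg1_mean_hue",
    "srm_seg1_mean_value",
    "srm_seg1_variance",
    "global_entropy",
    "srm_seg2_entropy",
    "intensity_bin_1",
    "intensity_bin_2",
    "presence_person",
]


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    level: str  # "low" | "high"
    scope: str  # "global" | "segment-1" | "segment-2"
    backend: str | None  # segmentation backend or None
    ref: str


@dataclass(frozen=True)
class FeatureCatalog:
    entries: tuple[CatalogEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("catalog names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def level_of(self, name: str) -> str:
        for e in self.entries:
            if e.name == name:
                return e.level
        raise KeyError(name)

    def names_at_level(self, level: str) -> list[str]:
        return [e.name for e in self.entries if e.level == level]

    def subset(self, names: Iterable[str]) -> "FeatureCatalog":
        wanted = list(names)
        by_name = {e.name: e for e in self.entries}
        return FeatureCatalog(tuple(by_name[n] for n in wanted))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(e) for e in self.entries], fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureCatalog":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(tuple(CatalogEntry(**e) for e in raw))


def build_catalog() -> FeatureCatalog:
    """Assemble the full 83-entry candidate registry."""
    entries: list[CatalogEntry] = []

    for name in GRAPH_GLOBALS:
        entries.append(CatalogEntry(name, "low", "global", "graph", "global statistic"))
    for s in (1, 2):
        for feat in GRAPH_LOCALS:
            entries.append(
                CatalogEntry(f"graph_seg{s}_{feat}", "low", f"segment-{s}", "graph",
                             "segment statistic")
            )
    for s in (1, 2):
        for feat in SRM_LOCALS:
            entries.append(
                CatalogEntry(f"srm_seg{s}_{feat}", "low", f"segment-{s}", "srm",
                             "segment statistic")
            )
    for s in (1, 2):
        for feat in KMEANS_LOCALS:
            entries.append(
                CatalogEntry(f"kmeans_seg{s}_{feat}", "low", f"segment-{s}",
                             "kmeans_lab", "segment statistic")
            )
    for name in EXTRA_GLOBALS:
        entries.append(CatalogEntry(name, "low", "global", None, "global statistic"))

    for name in HIGH_LEVEL:
        ref = "annotated attribute"
        if name == "presence_person":
            ref = "annotated attribute; pooled with low-level candidates at selection"
        entries.append(CatalogEntry(name, "high", "global", None, ref))

    return FeatureCatalog(tuple(entries))


def selection_candidate_names(catalog: FeatureCatalog) -> list[str]:
    """The candidate pool for the first (low-level) selection stage.

    All pixel-computable features plus presence-of-a-person, which entered
    the pool before its reclassification: 79 names for the full catalog.
    """
    return catalog.names_at_level("low") + ["presence_person"]
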