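"""Generate procedural stimuli and extract the candidate feature bank.

Writes the full 83-column feature table (TSV), the catalog registry (JSON)
and the generator manifest under results/.  The stimuli are solid-shape
compositions with known segment structure, so the extracted features can be
checked against the constructor's intent (largest-segment size, symmetry,
blur level).
"""

import json
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from artvalue.catalog import build_catalog
from artvalue.pipeline import extract_stimulus_features

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 0
N_IMAGES = 120


def main() -> None:
    catalog = build_catalog()
    catalog.to_json(OUT / "feature_catalog.json")
    print(f"catalog: {len(catalog)} features "
          f"({len(catalog.names_at_level('low'))} low, "
          f"{len(catalog.names_at_level('high'))} high)")

    table, manifest = extract_stimulus_features(n_images=N_IMAGES, seed=SEED)
    table.to_csv(OUT / "stimulus_features.tsv", sep="\t", index_label="stimulus")
    with open(OUT / "stimulus_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    assert np.isfinite(table.values).all(), "feature table contains NaN"
    print(f"extracted {table.shape[0]} stimuli x {table.shape[1]} features "
          f"-> {OUT / 'stimulus_features.tsv'}")


if __name__ == "__main__":
    main()
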