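"""Build nonlinear interaction features from the shared set.

Forms all pairwise products within and across the low/high levels of the
shared feature set (z-scored first), reduces each of the three groups to
five principal components, and writes the 15-column interaction table.
"""

import json
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from artvalue.catalog import SHARED_FEATURE_NAMES, build_catalog
from artvalue.interactions import build_interaction_groups, reduce_groups

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    catalog = build_catalog()
    features = pd.read_csv(OUT / "stimulus_features.tsv", sep="\t",
                           index_col="stimulus")
    shared = features[[c for c in SHARED_FEATURE_NAMES if c in features.columns]]
    shared = shared.loc[:, shared.std() > 0]
    levels = {c: catalog.level_of(c) for c in shared.columns}

    groups = build_interaction_groups(shared, levels)
    sizes = {k: int(v.shape[1]) for k, v in groups.matrices.items()}
    reduced, _ = reduce_groups(groups, n_pcs=5)
    reduced.to_csv(OUT / "interaction_features.tsv", sep="\t",
                   index_label="stimulus")
    with open(OUT / "interaction_summary.json", "w") as fh:
        json.dump({"group_sizes": sizes, "n_pc_columns": int(reduced.shape[1])},
                  fh, indent=1)
    print(f"interaction group sizes: {sizes}")
    print(f"reduced to {reduced.shape[1]} PC columns "
          f"-> {OUT / 'interaction_features.tsv'}")


if __name__ == "__main__":
    main()
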