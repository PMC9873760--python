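"""Group-level shared-feature selection on a planted cohort.

Runs the sparse-PCA + group-lasso (FISTA) + back-mapping + dedup pipeline
on synthetic cohorts whose ratings are driven by a known feature subset,
and reports how often the planted support is recovered exactly.  Also
writes the fixed shared feature registry used by the neural analyses.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from artvalue.catalog import SHARED_FEATURE_NAMES, build_catalog
from artvalue.pipeline import support_recovery

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    catalog = build_catalog()
    shared = {
        "names": SHARED_FEATURE_NAMES,
        "levels": {n: catalog.level_of(n) for n in SHARED_FEATURE_NAMES},
    }
    with open(OUT / "shared_feature_set.json", "w") as fh:
        json.dump(shared, fh, indent=1)
    print(f"shared feature set: {len(SHARED_FEATURE_NAMES)} features "
          f"({sum(1 for v in shared['levels'].values() if v == 'low')} low, "
          f"{sum(1 for v in shared['levels'].values() if v == 'high')} high)")

    rec = support_recovery(n_seeds=20, seed=SEED)
    with open(OUT / "support_recovery.json", "w") as fh:
        json.dump(rec, fh, indent=1)
    print(f"planted-support recovery: {rec['rate']:.2f} over {rec['n_seeds']} seeds")


if __name__ == "__main__":
    main()
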