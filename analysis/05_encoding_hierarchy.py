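"""Voxelwise encoding of low/high features across a planted ROI gradient.

Simulates multi-region BOLD in which ordered visual ROIs weight low- versus
high-level feature signal along a gradient (g = 0.1 ... 0.9), fits the
feature GLM, runs group F-tests per voxel, and reports the per-ROI
proportion profiles and the hierarchy index (rank correlation of ROI order
with the high-minus-low significant-voxel proportion difference).  Also
reports the F-test's null calibration on pure-noise voxels.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from artvalue.pipeline import encoding_hierarchy, f_test_calibration

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    res = encoding_hierarchy(seed=SEED, n_seeds=10)
    res["example_profile"].to_csv(OUT / "roi_proportion_profile.tsv", sep="\t",
                                  index_label="roi")
    cal = f_test_calibration(seed=SEED)
    with open(OUT / "encoding_hierarchy.json", "w") as fh:
        json.dump(
            {
                "hierarchy_index_mean": res["hierarchy_index_mean"],
                "recovery_rate": res["recovery_rate"],
                "hierarchy_indices": res["hierarchy_indices"],
                "f_test_calibration": cal,
            },
            fh, indent=1,
        )
    print("example ROI proportion profile (fraction of significant voxels):")
    print(res["example_profile"].round(2))
    print(f"hierarchy index mean {res['hierarchy_index_mean']:.2f}; "
          f"recovered (>= 0.8) in {res['recovery_rate']:.0%} of sessions")
    print(f"F-test null rejection at alpha={cal['alpha']}: "
          f"{cal['rejection_rate']:.4f}")


if __name__ == "__main__":
    main()
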