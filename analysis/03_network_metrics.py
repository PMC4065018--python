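#!/usr/bin/env python
"""Per-subject network metrics: voxel sets, median PiB, r_GLOBAL.

For every subject and network: select the voxels with connectivity z > 1,
extract the paired PiB values, and compute the median network PiB uptake,
the median log-connectivity score, and the whole-network Pearson
correlation between log-connectivity and PiB (r_GLOBAL, with its Fisher
transform).  The searchlight stage follows in the next script.
"""

from pathlib import Path

from amynet.pipeline import cohort_metrics
from amynet.synthetic import load_cohort

ROOT = Path(__file__).resolve().parents[1]

def main() -> None:
    subjects = load_cohort(ROOT / "scratch" / "cohort" / "manifest.csv")
    df, _ = cohort_metrics(subjects, compute_rlocal=False)
    df.to_csv(ROOT / "results" / "global_metrics.csv", index=False, float_format="%.10g")
    print(f"{len(df)} subject x network rows; "
          f"median network size {df.n_voxels.median():.0f} voxels")
    print("\nmean r_GLOBAL by group and network:")
    print(df.pivot_table(index="network", columns="group", values="r_global",
                         sort=False).round(3))
    print("\nmean median-PiB by group and network:")
    print(df.pivot_table(index="network", columns="group", values="median_pib",
                         sort=False).round(3))


if __name__ == "__main__":
    main()
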