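"""Position-wise group comparison on a synthetic cohort.

Generates a small sham/TBI cohort whose injured animals carry the
default lesion pattern, computes axis profiles of every parameter map,
and runs the Mann-Whitney grid with Benjamini-Hochberg FDR control.
"""

from hippoaxis.profiles import cohort_profiles
from hippoaxis.stats import profile_group_comparison
from hippoaxis.synthetic import CohortConfig, generate_cohort

cfg = CohortConfig(n_sham=10, n_tbi=16, seed=4, voxel_dims=(0.3, 0.3, 0.5),
                   store_truth=False)
records, labels = generate_cohort(cfg)
table = cohort_profiles(records, axis_mode="true", spacing=1.0)

grid = profile_group_comparison(table, labels, "sham_tbi", q_level=0.05,
                                auc_ci=False)
rejected = grid[grid["reject"]]
print(f"{len(rejected)} of {len(grid)} cells differ between sham and TBI "
      f"after FDR control")
summary = (rejected.groupby(["side", "day", "parameter", "statistic"])
           ["position_mm"].agg(["min", "max", "count"]))
print(summary.head(12).to_string())
# Rejections concentrate in the cells where the generator injects injury
# effects (e.g. ipsilateral T2 mean at D2 along the whole axis); the
# epilepsy contrast on the same cohort yields (almost) no rejections
# because no epilepsy effect is simulated.
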