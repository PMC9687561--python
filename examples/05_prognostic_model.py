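"""Elastic-net prognostic model with nested leave-one-out CV.

Assembles the 48-predictor feature matrix (mean and SD of every
parameter-day map) at one axis position, fits the class-weighted
elastic-net logistic regression inside a nested LOOCV, and reports the
pooled cross-validated AUC with its BCa bootstrap confidence interval
plus the most important predictors.
"""

from hippoaxis.model import (
    assemble_features,
    coefficient_importance,
    format_auc,
    model_auc_with_ci,
    nested_loocv_elastic_net,
)
from hippoaxis.profiles import cohort_profiles
from hippoaxis.stats import contrast_labels
from hippoaxis.synthetic import CohortConfig, generate_cohort

cfg = CohortConfig(n_sham=10, n_tbi=16, seed=5, voxel_dims=(0.3, 0.3, 0.5),
                   store_truth=False)
records, labels = generate_cohort(cfg)
table = cohort_profiles(records, positions=[9.0], axis_mode="true")

y = contrast_labels(labels, "sham_tbi")
X = assemble_features(table, 9.0, "ipsi")
result = nested_loocv_elastic_net(X, y.loc[X.index].to_numpy(), mixing=0.5,
                                  seed=0, inner="kfold", n_inner=5,
                                  n_lambda=30, lambda_min_ratio=1e-2)
model_auc_with_ci(result, n_boot=2000, seed=1)
print("sham vs TBI at 9.0 mm (ipsilateral):", format_auc(result))

imp = coefficient_importance(result, k=5)
print("top predictors (fold-averaged standardized coefficients):")
for name in imp.attrs["top_predictors"]:
    print(f"  {name:16s} {imp.loc[name].iloc[0]:+.3f}")
# With the injected injury pattern the model separates the groups
# (AUC near 1.0) and ranks injected predictors such as the early T2
# increase at the top.
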