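"""Predict the lesion subset from non-imaging clinical features alone.

Fits the screening -> PCA -> tuned random-forest classifier on a synthetic
cohort and reports its accuracy and multiclass Matthews correlation.
"""

import pandas as pd

from lesioncast import (
    CohortSpec,
    cluster_subjects,
    default_atlas,
    fit_subset_pipeline,
    generate_cohort,
    generate_features,
    multiclass_mcc,
    predict_subset,
)
from sklearn.metrics import confusion_matrix

atlas = default_atlas()
spec = CohortSpec(seed=2)
lesion, truth = generate_cohort(spec, atlas)
features, _ = generate_features(lesion, spec)
subsets = cluster_subjects(truth[["occurrence", "sparsity"]], k=3, seed=2)["subset"]

clf = fit_subset_pipeline(
    features, subsets.to_numpy(), seed=2,
    grid={"n_estimators": [100], "max_depth": [None, 5]}, n_resamples=5,
)
pred = predict_subset(clf, features)
cm = confusion_matrix(subsets, pred)
print(f"retained {len(clf.screened_features)} features "
      f"-> {clf.reduction.n_components} principal components")
print("confusion matrix (rows = true subset):")
print(pd.DataFrame(cm, index=[1, 2, 3], columns=[1, 2, 3]))
print(f"accuracy: {(pred == subsets.to_numpy()).mean():.1%}  "
      f"MCC: {multiclass_mcc(cm):.2f}")
# the classifier assigns new patients to a subset without any imaging, so
# subset-specific lesion models can be chosen from clinical scores alone.
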