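"""Confusion matrix, diagnostic metrics and ROC for one held-out evaluation.

Trains a KNN on one stratified split and reports the binary diagnostic
metrics (malignant-like class positive) plus the ROC area computed from the
neighbour-vote scores.  Youden's J = sensitivity + specificity - 1 summarizes
informedness: 0 is chance, 1 is a perfect test.
"""

import numpy as np

from wavelstm import (
    BaselineConfig,
    GeneratorConfig,
    binary_metrics,
    confusion_matrix,
    fit_baseline,
    generate_feature_dataset,
    make_split_plan,
    roc_points,
)

data = generate_feature_dataset(GeneratorConfig(
    n_per_class=30, dim=64, sparsity=0.8,
    spike_rate_per_class=(8.0, 2.0), spike_scale=12.0, noise_sd=0.02, seed=42,
))
plan = make_split_plan(data.labels, repeats=1, seed=5)
tr, te = plan.splits[0]

model = fit_baseline(data.features[tr], data.labels[tr], BaselineConfig(k=5))
pred = model.estimator.predict(data.features[te])
scores = model.estimator.predict_proba(data.features[te])[:, 1]

cm = confusion_matrix(data.labels[te], pred, 2)
print("confusion matrix (rows = true, cols = predicted):")
print(cm)

report = binary_metrics(cm)
print(f"accuracy    {report.accuracy:5.1f} %")
print(f"sensitivity {report.sensitivity:5.1f} %")
print(f"specificity {report.specificity:5.1f} %")
print(f"Youden's J  {report.youden:5.2f}")

fpr, tpr, area = roc_points(scores, data.labels[te])
print(f"ROC: {len(fpr)} operating points, area {area:.3f}")
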