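"""Leakage-controlled LOOCV classification of embryo developmental competence.

Every fold standardizes, SMOTE-balances and PCA-rotates its own training set;
the held-out sample is only transformed. The pooled confusion matrix and
rank-based ROC AUC are compared against the majority-class dummy baseline
(AUC 0.5 by construction).
"""

from micromrs import (
    PipelineConfig,
    build_feature_table,
    dummy_baseline,
    generate_cohort,
    loocv,
    metrics,
    preset_config,
)

spectra, labels = generate_cohort(preset_config("embryo61", seed=0))
table = build_feature_table(spectra, labels)

cv = loocv(table, PipelineConfig(seed=0))
rep = metrics(cv)
dummy = dummy_baseline(table)

print(f"confusion (positive=DEV): TP={rep.tp} FN={rep.fn} FP={rep.fp} TN={rep.tn}")
print(f"accuracy          {rep.accuracy:.3f}")
print(f"balanced accuracy {rep.balanced_accuracy:.3f}")
print(f"sensitivity       {rep.sensitivity:.3f}")
print(f"precision         {rep.precision:.3f}")
print(f"NPV               {rep.npv:.3f}")
print(f"F1                {rep.f1:.3f}")
print(f"AUC               {rep.auc:.3f}   (dummy baseline: {dummy.auc:.1f})")
print("\nAUC well above 0.5 shows the biomarker panel carries predictive "
      "signal for the planted cohort effects under honest cross-validation.")
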