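"""Sepsis diagnosis and recovery prognosis on a synthetic patient cohort.

Builds a 444-patient cohort with septic effect structure, compares the
Quick-SIRS feature set (temperature, pulse, respirations, systolic blood
pressure) against Quick SIRS plus the biochip panel (lactic acid, nCD64,
total leukocytes and differentials) under repeated 10-fold cross-validated
linear SVM, then trains the per-time-window prognosis network.
"""

from impedcyto import FeatureSetSpec, ann_prognosis, compare_feature_sets
from impedcyto.sim import CohortConfig, simulate_cohort

cohort = simulate_cohort(CohortConfig(n_patients=444), seed=5)
tw1 = cohort[cohort.time_window == "TW1"].reset_index(drop=True)

res = compare_feature_sets(
    tw1,
    FeatureSetSpec.quick_sirs(),
    FeatureSetSpec.quick_sirs_plus_biochip(),
    folds=10,
    iterations=50,
    seed=5,
)
print(f"Quick SIRS mean AUC:            {res['result_a'].mean_auc:.3f}")
print(f"+ biochip panel mean AUC:       {res['result_b'].mean_auc:.3f}")
print(f"one-sided paired Wilcoxon p:    {res['p_value']:.2e}")
print("feature ranking (mean |SVM weight|):")
for name, weight in list(res["result_b"].feature_importance.items())[:4]:
    print(f"  {name:12s} {weight:.3f}")

prognosis_cohort = simulate_cohort(
    CohortConfig(n_patients=160, septic_fraction=1.0, deceased_fraction_septic=0.4),
    seed=6,
)
for window in ("TW1", "TW5", "TW6"):
    ann = ann_prognosis(prognosis_cohort, window, seed=1)
    print(f"prognosis ANN test AUC at {window}: {ann['auc']:.3f} "
          f"(n_test={ann['n_test']})")
# The AUC gain with the biochip features, significant under the paired
# Wilcoxon test, is the stratification value the added biomarkers carry;
# late windows separate survivors from non-survivors most sharply because
# a resolving nCD64 falls while a non-resolving one keeps rising.
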