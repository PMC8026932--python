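"""Leave-one-out evaluation of the balanced-ensemble classifier.

Uses a feature-level synthetic cohort (8 recurrence / 16 no-recurrence, a
clear class gap on four features) so the run takes seconds, and evaluates
the KNN family: per held-out patient, seven class-balanced subsets each run
sequential forward selection (<= 3 features) and vote; the majority decides.
Prints the confusion matrix, the headline metrics and how often each
feature was selected across all subsets and folds.
"""

from qusrecur import classify, features

table = features.synthetic_feature_table(seed=0)
config = classify.ClassifierConfig(family="knn", seed=1)
folds, report = classify.loo_evaluate(table, config)

print(f"n = {report.n} patients, family = {report.family}")
print(f"confusion: TP {report.tp}  FN {report.fn}  "
      f"TN {report.tn}  FP {report.fp}")
print(f"sensitivity {report.sensitivity:.1f} %  "
      f"specificity {report.specificity:.1f} %  "
      f"accuracy {report.accuracy:.1f} %  AUC {report.auc:.3f}")
top = sorted(report.feature_frequency.items(), key=lambda kv: -kv[1])[:5]
print("most selected features (subset x fold counts):")
for name, count in top:
    print(f"  {name:8s} {count}")
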