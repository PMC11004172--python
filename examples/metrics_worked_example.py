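"""One-vs-rest diagnostic metrics from a clinical confusion table.

A 56-patient test set with 10 true AML cases: 8 detected (sensitivity 8/10)
and 3 false alarms among 46 non-AML patients (specificity 43/46). The
metrics engine turns those counts into the standard screening columns.
"""

from leukoflow.evaluation import confusion_counts, metrics_from_counts, percent

tp, fp, fn, tn = 8, 3, 2, 43
m = metrics_from_counts(tp, fp, fn, tn)
print(f"counts: TP={tp} FP={fp} FN={fn} TN={tn} (n={tp + fp + fn + tn})")
for key in ("f1", "accuracy", "sensitivity", "specificity"):
    print(f"  {key:<12} {percent(m[key])}")
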