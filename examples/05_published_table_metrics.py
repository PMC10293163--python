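"""Performance metrics from a published held-out confusion table.

Feeds the three confusion-table column blocks of the reference clinical
study (combined, SCD-only, MCI-only; 76 held-out subjects) through the
package's metric computation and prints sensitivity / specificity /
accuracy with the table's one-decimal rounding.
"""

from amyeeg.evaluate import ConfusionMatrix, metrics

tables = {
    "SCD+MCI": ConfusionMatrix(tp=30, fp=10, fn=3, tn=33),
    "SCD only": ConfusionMatrix(tp=12, fp=6, fn=1, tn=18),
    "MCI only": ConfusionMatrix(tp=18, fp=4, fn=2, tn=15),
}

for name, cm in tables.items():
    rep = metrics(cm)
    print(f"{name:9s} (n={cm.total:2d}): sensitivity {rep.sensitivity_pct}%, "
          f"specificity {rep.specificity_pct}%, accuracy {rep.accuracy_pct}%")
print("Sensitivity = TP/(TP+FN) among amyloid-positive subjects; specificity =")
print("TN/(TN+FP) among negatives; the SCD and MCI blocks sum cell-wise to the")
print("combined block.")
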