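"""Cohort census and effect detection on synthetic ground truth.

Loads the shipped 14-patient lesion table, prints the census, then
generates a synthetic cohort with a doubling week-4 -> week-10 Ktrans
effect in progressors and tests whether the change discriminates them.
"""

import numpy as np

from dcekin import (
    ProgressionEffect,
    compare_groups,
    generate_cohort,
    lesion_census,
    load_example_cohort,
    roc_auc,
)

census = lesion_census(load_example_cohort())
print(f"cohort: {census['n_patients']} patients, {census['total_lesions']} lesions, "
      f"{census['n_progressors']} progressors at 6 months")
for organ, n in sorted(census["by_organ"].items(), key=lambda kv: -kv[1]):
    print(f"  {organ}: {n}")

_, truth = generate_cohort(n_patients=14, n_progressors=3,
                           effect=ProgressionEffect(ktrans_rise_factor=2.0), seed=1)
wide = truth.pivot_table(index=["patient_id", "lesion_id"], columns="timepoint",
                         values="ktrans_true").reset_index()
wide["change"] = wide["week10"] - wide["week4"]
prog = truth.drop_duplicates("patient_id").set_index("patient_id")["progression"]
labels = (wide["patient_id"].map(prog) == "yes").values
changes = wide["change"].values

res = compare_groups(changes[labels], changes[~labels])
auc = roc_auc(changes, labels).auc
print(f"\nweek4 -> week10 true Ktrans change: {res.test_name} p = {res.p_value:.4f} "
      f"({res.route}), AUC = {auc:.3f}")
# Progressors' Ktrans rebounds after the initial treatment-induced fall, so
# the change separates the groups (AUC 1.0 on noiseless truth) — the rank
# signature the response analysis is designed to pick up.
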