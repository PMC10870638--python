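"""Simulate two age groups and run the descriptive comparison battery.

Draws a younger and an older sample from the calibrated latent factor
model, splits them at age 60 and compares occurrence (Fisher's exact),
printing the mean symptom count per group, the number of significantly
differing symptoms, and each group's top-10 occurrence ranking.
"""

import numpy as np

from symclust import (
    compare_groups,
    default_generating_model,
    dichotomize_by_age,
    mean_symptom_count,
    occurrence_rates,
    rank_top_symptoms,
    simulate_group,
)
from symclust.dataset import SymptomDataset

young = simulate_group(default_generating_model("younger", n=741, seed=11))
old = simulate_group(default_generating_model("older", n=602, seed=12))
combined = SymptomDataset(
    young.catalog,
    young.patient_ids + old.patient_ids,
    np.concatenate([young.ages, old.ages]),
    np.vstack([young.occurrence, old.occurrence]),
    np.vstack([young.severity, old.severity]),
    np.vstack([young.distress, old.distress]),
    provenance="example",
)

split = dichotomize_by_age(combined, cutoff=60.0)
rows, n_sig = compare_groups(split, alpha=0.05)

for name, ds in (("younger", split.younger), ("older", split.older)):
    mean, sd = mean_symptom_count(ds)
    print(f"{name}: n={ds.n}, mean symptom count {mean:.1f} (SD {sd:.1f})")
print(f"{n_sig} of 38 symptoms differ in occurrence at p < 0.05")
# Under the calibrated model the younger group carries the higher symptom
# burden, mirroring the occurrence rates the generator was built from.

for name, ds in (("younger", split.younger), ("older", split.older)):
    ranked = rank_top_symptoms(occurrence_rates(ds) * 100, k=10)
    print(f"\ntop occurrence, {name} group:")
    for code, pct, rank in ranked.entries:
        print(f"  {rank:>2}. {code:<28} {pct:5.1f}%")
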