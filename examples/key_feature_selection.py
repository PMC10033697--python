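"""Physical key feature selection (PKFS) with planted ground truth.

Per activity class, features are ranked by precedence (total occurrence
frequency in the class) with an instance-support floor u_i and a
per-class budget u_f; the per-class picks merge into a deduplicated
union set.  On simulated data with 5 planted informative sensors per
activity, the union should recover the planted sensors.
"""

from keysense import SelectionConfig, select_key_features
from keysense.simulate import SimulationConfig, make_cohort_dataset, planted_recall

matrix, truth = make_cohort_dataset(SimulationConfig(seed=3))
result = select_key_features(matrix, SelectionConfig(u_f=7, u_i=2))

print("top features per activity (feature, precedence = class-total frequency):")
for label in (1, 2):
    picks = ", ".join(f"{n} ({p:.0f})" for n, p in result.per_class[label][:4])
    print(f"  activity {label}: {picks}, ...")
print(f"\nunion key-feature set: {len(result.union_set)} features "
      f"(deduplicated across 8 activities)")
recall = planted_recall(result, truth)
print(f"planted-sensor recovery recall: {recall:.2f} "
      f"(fraction of the 40 planted informative sensors present in the union)")
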