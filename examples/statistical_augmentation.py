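"""Statistical key feature augmentation (SKFS).

Each instance's selected-feature vector is summarized by 13 statistics
(moments, quantiles, crossing rates, lag-1 autocorrelation, spectral
entropy) which are appended as extra columns, giving the classifier a
scale-free fingerprint of the instance on top of the raw counts.
"""

from keysense import SelectionConfig, augment, fit_scaler, rescale, row_statistics, select_key_features
from keysense.simulate import SimulationConfig, make_cohort_dataset

stats = row_statistics([1.0, -1.0, 1.0, -1.0])
print("statistics of the alternating vector (1, -1, 1, -1):")
print(f"  mean {stats['mean']:.1f}, rms {stats['rms']:.1f}, "
      f"zero-crossing rate {stats['zero_crossing_rate']:.2f} (a crossing at every step),")
print(f"  avg derivative {stats['avg_derivative']:.3f}, "
      f"lag-1 autocorrelation {stats['pairwise_correlation']:.2f}")

matrix, _ = make_cohort_dataset(SimulationConfig(n_healthy=6, n_dementia=2, seed=4))
selection = select_key_features(matrix, SelectionConfig(u_f=7, u_i=2))
scaled = rescale(matrix, fit_scaler(matrix))
augmented = augment(scaled, selection)
print(f"\nselected {len(selection.union_set)} union features; after augmentation the "
      f"matrix has {len(augmented.feature_names)} columns "
      f"({len(selection.union_set)} selected + 13 statistics)")
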