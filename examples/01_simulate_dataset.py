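"""Generate a synthetic four-group LC-MS feature table with ground truth.

The generator plants class effects, a rank-one batch artifact, per-sample
dilution and log-normal noise; the returned GroundTruth holds the true
values so downstream recovery can be verified.
"""

import chemometab as cm

config = cm.SimulationConfig(seed=1)
table, truth = cm.generate_dataset(config)

print(f"samples: {table.n_samples} ({int(table.is_qc.sum())} QCs), features: {table.n_features}")
print("class counts:")
print(table.sample_meta.loc[~table.is_qc, "class"].value_counts().to_string())
print(f"informative features: {len(truth.informative_ids)} "
      f"(first five: {truth.informative_ids[:5]})")
print(f"dilution factors span {truth.dilution_factors.min():.2f}-"
      f"{truth.dilution_factors.max():.2f}")
# Each class row of the shift matrix holds the true log10 intensity shifts;
# CTRL is all zero, treated classes carry +-effect_size on their marker block.
print("true shift matrix shape (classes x informative):", truth.class_shift_matrix.shape)
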