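"""Find a batch-dominated principal component, remove it, reconstruct.

A diagnostic ranking (here against the simulator's true batch scores;
on real data one would use injection order or QC behaviour) identifies
the artifact PC; subtracting its score-loading product removes exactly
that direction while keeping all other variance.
"""

import numpy as np

import chemometab as cm

config = cm.SimulationConfig(seed=3, batch_sd=1.0, effect_size=0.3, noise_sd=0.1)
table, truth = cm.generate_dataset(config)
pre, _ = cm.preprocess_table(table)
Z = pre.values()

model = cm.fit_pca(Z, 5)
print("explained variance fractions:", np.round(model.explained_fraction, 3))
ranking = cm.rank_components_by_correlation(model, truth.batch_scores)
print("PCs ranked by |correlation| with the batch covariate:")
print(ranking.to_string(index=False))

batch_pc = int(ranking.iloc[0]["component"])
Z_rec = cm.remove_components_and_reconstruct(Z, model, {batch_pc})
print(f"projection onto dropped PC{batch_pc} after removal: "
      f"{abs(Z_rec @ model.loadings[:, batch_pc - 1]).max():.1e}")

refit = cm.fit_pca(Z_rec, 4)
cos = abs(refit.loadings.T @ truth.batch_loading).max()
print(f"max |cosine| of refit loadings with the true batch direction: {cos:.3f}")
# values near zero mean the artifact is gone and only biology remains

ellipse = cm.hotelling_ellipse(refit.scores[:20, :2], confidence=0.95)
print(f"example Hotelling ellipse: semi-axes {np.round(ellipse.semi_axes, 2)}, "
      f"angle {np.degrees(ellipse.angle):.1f} deg")
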