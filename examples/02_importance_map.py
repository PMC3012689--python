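"""Fit the classifier on all trials and extract the importance map.

The importance of each channel x time cell is the posterior variance of
its auxiliary scale variables, relative to the prior variance: cells that
drive classification retain large coefficient scales after seeing the
data.  The map below should concentrate on the cells where the simulated
category effect was injected (channels 2-5, 10-70 ms).
"""

import numpy as np

import erpdecode as ed

config = ed.SimulationConfig(
    n_channels=10,
    epoch_window=(-20.0, 80.0),
    n_trials_per_exemplar=80,
    exemplars=ed.default_exemplars(4),
    category_effect=[
        ed.EffectSpec(channels=(2, 3, 4, 5), time_window=(10.0, 70.0), amplitude=3.5)
    ],
    noise=ed.NoiseSpec(spatial_mixing_neighbors=0, temporal_ar_coefficient=0.5),
    seed=1,
)
dataset = ed.generate_dataset(config)
features = ed.standardize(ed.extract_features(dataset, (-20.0, 80.0)))
model = ed.ModelSpec(interval=(-20.0, 80.0)).build_model(features.feature_index)
fit = ed.fit(features, model)
print(f"EP fit: converged={fit.converged} after {fit.n_sweeps} sweeps")

imap = ed.importance_map(fit, features.feature_index, model.prior_variances())
top = imap.top_cells(0.1)
mask = dataset.ground_truth_mask
overlap = (top & mask).sum() / top.sum()
print(f"top-decile cells inside the true effect mask: {overlap:.0%}")
print("per-channel mean importance (effect channels are 2-5):")
for ch, val in zip(imap.channels, imap.values.mean(axis=1)):
    print(f"  channel {ch}: {val:.3f}")
print("values are posterior/prior auxiliary-variance ratios; 1 means the "
      "data left that cell's prior scale untouched.")

table = imap.to_table()
table.to_csv("importance_map.tsv", sep="\t", index=False)
print(f"full map written to importance_map.tsv ({len(table)} rows)")
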