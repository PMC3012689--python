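"""Time-resolved decoding: independent analyses in consecutive 40-ms windows.

The default windowing covers 0-640 ms after stimulus onset in 16 windows.
The simulated category effect lives at 80-120 ms, so accuracy should peak
in that window and hover at chance elsewhere.
"""

import erpdecode as ed

config = ed.SimulationConfig(
    n_channels=6,
    epoch_window=(-40.0, 660.0),
    n_trials_per_exemplar=20,
    exemplars=ed.default_exemplars(2),
    category_effect=[
        ed.EffectSpec(channels=(1, 2), time_window=(80.0, 120.0), amplitude=10.0)
    ],
    noise=ed.NoiseSpec(spatial_mixing_neighbors=0, temporal_ar_coefficient=0.5),
    seed=4,
)
dataset = ed.generate_dataset(config)
report = ed.sliding_window(dataset, ed.ModelSpec(), scheme=ed.CVScheme(k=2, seed=0))

print(report.table[["unit", "accuracy", "p_value"]].to_string(index=False))
best = report.table.loc[report.table.accuracy.idxmax()]
print(f"\nbest window: {best.unit} at accuracy {best.accuracy:.3f} "
      f"(effect was injected at 80-120 ms)")
print("Each row is a full cross-validated analysis restricted to one "
      "40-ms window; chance level is 0.5.")
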