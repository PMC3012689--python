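"""Joint decoding of three sessions with a cross-dataset coupled prior.

Each session keeps its own regression coefficients, but the prior scales
of corresponding channel x time features are coupled across sessions
through the multivariate Laplace precision matrix, so features carrying
shared category information are favoured in every session.
"""

import erpdecode as ed

datasets = [
    ed.generate_dataset(
        ed.SimulationConfig(
            n_channels=8,
            epoch_window=(-10.0, 40.0),
            n_trials_per_exemplar=20,
            exemplars=ed.default_exemplars(4),
            category_effect=[
                ed.EffectSpec(channels=(2, 3), time_window=(10.0, 40.0), amplitude=7.0)
            ],
            noise=ed.NoiseSpec(spatial_mixing_neighbors=0,
                               temporal_ar_coefficient=0.5),
            seed=seed,
            modality=name,
        )
    )
    for seed, name in [(21, "pictures"), (22, "spoken"), (23, "written")]
]

report = ed.transfer_learning(
    datasets, ed.ModelSpec(interval=(-10.0, 40.0)), ed.CVScheme(k=5, seed=0)
)
print(report.table.to_string(index=False))

imap = report.importance["joint"]
top = imap.top_cells(0.1)
mask = datasets[0].ground_truth_mask
print(f"\njoint importance: {100 * (top & mask).sum() / top.sum():.0f}% of "
      "top-decile cells lie on the shared effect (channels 2-3, 10-40 ms)")
print("One accuracy per session from fold-aligned CV of the joint fit; all "
      "should clear chance because the effect is shared.")
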