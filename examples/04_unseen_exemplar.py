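"""Category generalization to exemplars never seen during training.

Two simulated sessions contrast the outcomes the analysis is designed to
dissociate: one with a genuine category-general effect (the classifier
predicts the category of a held-out exemplar well above chance) and one
with purely exemplar-specific signatures (within-session CV is high, but
the held-out exemplar's category cannot be predicted).
"""

import erpdecode as ed

BASE = dict(
    n_channels=10,
    epoch_window=(-20.0, 80.0),
    n_trials_per_exemplar=40,
    exemplars=ed.default_exemplars(4),
    noise=ed.NoiseSpec(spatial_mixing_neighbors=0, temporal_ar_coefficient=0.5),
)
spec = ed.ModelSpec(interval=(-20.0, 80.0))

category_session = ed.generate_dataset(
    ed.SimulationConfig(
        category_effect=[
            ed.EffectSpec(channels=(2, 3, 4, 5), time_window=(10.0, 70.0), amplitude=6.0)
        ],
        seed=11,
        **BASE,
    )
)
exemplar_session = ed.generate_dataset(
    ed.SimulationConfig(
        exemplar_effect=[
            ed.EffectSpec(
                channels=tuple(range(10)), time_window=(10.0, 70.0),
                amplitude=2.5, scope="exemplar-specific",
            )
        ],
        seed=12,
        **BASE,
    )
)

for name, session in [("category-general", category_session),
                      ("exemplar-specific", exemplar_session)]:
    cv = ed.cross_validate(session, spec, ed.CVScheme(k=5, seed=0)).accuracy
    unseen = ed.unseen_exemplar(session, spec)
    print(f"{name:18s}: within-session CV {cv:.3f} | "
          f"unseen-exemplar {unseen.accuracy:.3f}")
print("\nHigh CV with chance-level unseen accuracy means the classifier "
      "identified exemplars, not categories — the interpretive control "
      "this analysis provides.")
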