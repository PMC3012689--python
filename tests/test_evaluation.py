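"""Cross-validation, sliding windows, unseen-exemplar, transfer, binomial."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import erpdecode as ed
from oracles import binomial_tail_sum

TINY_NOISE = dict(
    background_sd=8.0, temporal_ar_coefficient=0.5, spatial_mixing_neighbors=0
)


def _tiny(seed=0, amp=0.0, n_channels=4, n_per=8, window=(-10.0, 40.0),
          eff_window=(0.0, 30.0), exemplars=2, scope="category-general"):
    effects = []
    if amp > 0:
        effects = [
            ed.EffectSpec(
                channels=tuple(range(min(2, n_channels))),
                time_window=eff_window,
                amplitude=amp,
                scope=scope,
            )
        ]
    cfg = ed.SimulationConfig(
        n_channels=n_channels,
        epoch_window=window,
        n_trials_per_exemplar=n_per,
        exemplars=ed.default_exemplars(exemplars),
        category_effect=[e for e in effects if e.scope == "category-general"],
        exemplar_effect=[e for e in effects if e.scope == "exemplar-specific"],
        noise=ed.NoiseSpec(**TINY_NOISE),
        seed=seed,
    )
    return ed.generate_dataset(cfg)


class TestFolds:
    def test_five_folds_on_640_trials_are_balanced_partitions(self):
        """Stratified 5-fold on 640 balanced trials: folds of 128 trials,
        class-balanced within one trial, forming a true partition."""
        y = np.repeat([0, 1], 320)
        scheme = ed.CVScheme(k=5, seed=3)
        splits = scheme.splits(y)
        all_test = np.concatenate([te for _, te in splits])
        assert sorted(all_test) == list(range(640))  # disjoint + exhaustive
        for tr, te in splits:
            assert len(te) == 128
            counts = np.bincount(y[te])
            assert abs(counts[0] - counts[1]) <= 1
            assert set(tr) | set(te) == set(range(640))
            assert not set(tr) & set(te)

    def test_fold_count_validated(self):
        with pytest.raises(ValueError):
            ed.CVScheme(k=1)


class TestCrossValidate:
    def test_separable_data_decodes_above_95_percent(self, signal_dataset, small_spec):
        rep = ed.cross_validate(signal_dataset, small_spec, ed.CVScheme(k=5, seed=0))
        assert rep.accuracy >= 0.95

    def test_label_shuffled_data_at_chance(self, signal_dataset, small_spec):
        """Destroying the label-data pairing drops accuracy into the 99%
        binomial band around 0.5."""
        rng = np.random.default_rng(5)
        shuffled = ed.EpochedDataset(
            data=signal_dataset.data,
            times=signal_dataset.times,
            labels=rng.permutation(signal_dataset.labels),
            exemplar_ids=signal_dataset.exemplar_ids,
            sampling_rate=signal_dataset.sampling_rate,
        )
        rep = ed.cross_validate(shuffled, small_spec, ed.CVScheme(k=5, seed=0))
        n = shuffled.n_trials
        half_width = 2.576 * np.sqrt(0.25 / n)
        assert abs(rep.accuracy - 0.5) <= half_width

    def test_accuracy_recomputable_from_predictions(self, signal_dataset, small_spec):
        rep = ed.cross_validate(signal_dataset, small_spec, ed.CVScheme(k=3, seed=1))
        recomputed = (
            rep.predictions.groupby("unit")
            .apply(
                lambda d: (d.y_true == d.y_pred).mean(),
                include_groups=False,
            )
            .mean()
        )
        assert np.isclose(rep.accuracy, recomputed)
        pooled = rep.table[rep.table.unit == "pooled"].iloc[0]
        assert pooled["n_correct"] == (rep.predictions.y_true == rep.predictions.y_pred).sum()

    def test_too_few_trials_per_class_rejected(self):
        ds = _tiny(n_per=2)
        with pytest.raises(ValueError, match="k trials per class"):
            ed.cross_validate(ds, ed.ModelSpec(interval=(-10.0, 40.0)), ed.CVScheme(k=5))


@pytest.fixture(scope="module")
def null_window_report():
    """Sliding-window analysis of a null dataset covering 0-640 ms."""
    cfg = ed.SimulationConfig(
        n_channels=4,
        epoch_window=(-40.0, 660.0),
        n_trials_per_exemplar=16,
        exemplars=ed.default_exemplars(2),
        noise=ed.NoiseSpec(**TINY_NOISE),
        seed=900,
    )
    ds = ed.generate_dataset(cfg)
    return ed.sliding_window(
        ds, ed.ModelSpec(), scheme=ed.CVScheme(k=2, seed=0)
    )


class TestSlidingWindow:
    def test_defaults_emit_sixteen_windows(self, null_window_report):
        assert len(null_window_report.table) == 16
        assert null_window_report.table.unit.iloc[0] == "0-40ms"
        assert null_window_report.table.unit.iloc[-1] == "600-640ms"
        assert len(null_window_report.importance) == 16

    def test_window_feature_count(self, null_window_report):
        imap = null_window_report.importance["0-40ms"]
        assert imap.values.shape == (4, 20)  # 40 ms at 2 ms/sample

    def test_null_accuracies_show_no_time_trend(self, null_window_report):
        """On signal-free data the per-window accuracies have no slope
        (95% CI of a linear fit covers zero)."""
        acc = null_window_report.table.accuracy.values
        res = stats.linregress(np.arange(16), acc)
        t = stats.t.ppf(0.975, 14)
        assert abs(res.slope) <= t * res.stderr

    def test_width_must_divide_interval(self, small_spec):
        ds = _tiny()
        with pytest.raises(ValueError, match="divide"):
            ed.sliding_window(ds, small_spec, width=37.0, start=0.0, end=40.0)

    def test_effect_localized_in_its_window(self):
        """An effect injected into the 80-120 ms window gives that window
        the highest decoding accuracy (mean over seeds)."""
        spec = ed.ModelSpec()
        scheme = ed.CVScheme(k=2, seed=0)
        gains = []
        for seed in range(3):
            cfg = ed.SimulationConfig(
                n_channels=4,
                epoch_window=(-40.0, 200.0),
                n_trials_per_exemplar=16,
                exemplars=ed.default_exemplars(2),
                category_effect=[
                    ed.EffectSpec(
                        channels=(0, 1), time_window=(80.0, 120.0), amplitude=12.0
                    )
                ],
                noise=ed.NoiseSpec(**TINY_NOISE),
                seed=910 + seed,
            )
            ds = ed.generate_dataset(cfg)
            rep = ed.sliding_window(
                ds, spec, width=40.0, start=0.0, end=160.0, scheme=scheme
            )
            acc = rep.table.set_index("unit").accuracy
            others = acc.drop("80-120ms")
            gains.append(acc["80-120ms"] - others.max())
        assert np.mean(gains) > 0


class TestUnseenExemplar:
    def test_eight_exemplars_give_eight_rows(self):
        ds = _tiny(seed=3, amp=8.0, exemplars=4, n_per=6)
        rep = ed.unseen_exemplar(ds, ed.ModelSpec(interval=(-10.0, 40.0)))
        assert len(rep.table) == 8
        assert set(rep.table.unit) == set(np.unique(ds.exemplar_ids))

    def test_needs_two_exemplars_per_category(self):
        ds = _tiny(seed=3, exemplars=1)
        with pytest.raises(ValueError, match="two exemplars"):
            ed.unseen_exemplar(ds, ed.ModelSpec(interval=(-10.0, 40.0)))


class TestTransferLearning:
    def _sets(self, seeds=(61, 62, 63), amp=8.0):
        out = []
        for s in seeds:
            cfg = ed.SimulationConfig(
                n_channels=4,
                epoch_window=(-10.0, 40.0),
                n_trials_per_exemplar=10,
                exemplars=ed.default_exemplars(2),
                category_effect=[
                    ed.EffectSpec(
                        channels=(0, 1), time_window=(0.0, 30.0), amplitude=amp
                    )
                ],
                noise=ed.NoiseSpec(**TINY_NOISE),
                seed=s,
                modality=f"m{s}",
            )
            out.append(ed.generate_dataset(cfg))
        return out

    def test_three_datasets_give_three_rows(self):
        rep = ed.transfer_learning(
            self._sets(), ed.ModelSpec(interval=(-10.0, 40.0)), ed.CVScheme(k=2, seed=0)
        )
        assert len(rep.table) == 3
        assert set(rep.importance) == {"m61", "m62", "m63", "joint"}

    def test_identical_copies_match_single_dataset_cv(self):
        """Coupling three copies of one dataset is degenerate: per-dataset
        accuracy stays within noise of the single-dataset CV accuracy."""
        ds = self._sets(seeds=(61,))[0]
        spec = ed.ModelSpec(interval=(-10.0, 40.0))
        scheme = ed.CVScheme(k=2, seed=0)
        single = ed.cross_validate(ds, spec, scheme).accuracy
        rep = ed.transfer_learning([ds, ds, ds], spec, scheme)
        assert np.abs(rep.table.accuracy - single).max() <= 0.15

    def test_mismatched_layout_rejected(self):
        a = self._sets(seeds=(61,))[0]
        cfg = ed.SimulationConfig(
            n_channels=6,
            epoch_window=(-10.0, 40.0),
            n_trials_per_exemplar=10,
            exemplars=ed.default_exemplars(2),
            noise=ed.NoiseSpec(**TINY_NOISE),
            seed=70,
        )
        b = ed.generate_dataset(cfg)
        with pytest.raises(ValueError, match="layout"):
            ed.transfer_learning([a, b], ed.ModelSpec(interval=(-10.0, 40.0)))


class TestBinomialSignificance:
    def test_baseline_performance_is_not_significant(self):
        """A classifier matching the majority-class baseline has p >= 0.5."""
        p, sig = ed.binomial_significance(50, 100, 0.5)
        assert p >= 0.5 and not sig
        p2, sig2 = ed.binomial_significance(65, 100, 0.65)
        assert p2 >= 0.4 and not sig2

    def test_matches_direct_pmf_summation(self):
        p, _ = ed.binomial_significance(65, 100, 0.5)
        assert abs(p - binomial_tail_sum(65, 100, 0.5)) < 1e-12

    def test_bonferroni_threshold(self):
        """alpha=0.05 over 20 subjects -> per-test threshold 0.0025."""
        n, p0 = 200, 0.5
        # find a count whose p lies between 0.0025 and 0.05
        for k in range(100, 140):
            p, _ = ed.binomial_significance(k, n, p0)
            if 0.0025 < p < 0.05:
                break
        _, sig_uncorr = ed.binomial_significance(k, n, p0, alpha=0.05, m_comparisons=1)
        _, sig_corr = ed.binomial_significance(k, n, p0, alpha=0.05, m_comparisons=20)
        assert sig_uncorr and not sig_corr

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ed.binomial_significance(5, 4, 0.5)
        with pytest.raises(ValueError):
            ed.binomial_significance(3, 4, 0.4)
        with pytest.raises(ValueError):
            ed.binomial_significance(3, 4, 0.5, m_comparisons=0)


def test_type_one_error_rate_controlled():
    """Over 200 signal-free simulations, the pooled binomial test at
    alpha=0.05 (m=1) flags at most 7.5% as significant."""
    spec = ed.ModelSpec(interval=(-10.0, 30.0))
    scheme = ed.CVScheme(k=2, seed=0)
    flags = []
    for seed in range(200):
        cfg = ed.SimulationConfig(
            n_channels=3,
            epoch_window=(-10.0, 30.0),
            n_trials_per_exemplar=15,
            exemplars=ed.default_exemplars(2),
            noise=ed.NoiseSpec(**TINY_NOISE),
            seed=2000 + seed,
        )
        ds = ed.generate_dataset(cfg)
        rep = ed.cross_validate(ds, spec, scheme)
        flags.append(bool(rep.table[rep.table.unit == "pooled"].significant.iloc[0]))
    assert np.mean(flags) <= 0.075
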