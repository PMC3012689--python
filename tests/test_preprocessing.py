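"""Preprocessing chain: filtering, epoching, rejection, features, scaling."""

from __future__ import annotations

import numpy as np
import pytest

import erpdecode as ed
from erpdecode.datasets import FeatureMatrix
from erpdecode.preprocessing import filter_continuous


def _sine_epochs(freq: float, fs: float = 500.0, n_samples: int = 500):
    t = np.arange(n_samples) / fs
    data = np.sin(2 * np.pi * freq * t)[None, None, :]
    return ed.EpochedDataset(
        data=data,
        times=-300.0 + 1000.0 / fs * np.arange(n_samples),
        labels=np.array(["a"]),
        exemplar_ids=np.array(["a0"]),
        sampling_rate=fs,
    )


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


class TestBandpass:
    def test_stopband_attenuation(self):
        """A 50 Hz sinusoid is attenuated by at least 20 dB by the 1-30 Hz
        band (zero-phase Butterworth; measured away from the segment edges,
        where filtfilt start-up transients dominate)."""
        ds = _sine_epochs(50.0, n_samples=2000)
        out = ed.bandpass_filter(ds, 1.0, 30.0)
        central = slice(500, 1500)
        assert _rms(out.data[..., central]) < 0.1 * _rms(ds.data)

    def test_passband_preserved(self):
        """A 10 Hz sinusoid passes the 1-30 Hz band with RMS within 10%."""
        ds = _sine_epochs(10.0)
        out = ed.bandpass_filter(ds, 1.0, 30.0)
        assert abs(_rms(out.data) / _rms(ds.data) - 1.0) < 0.1

    def test_zero_signal_stays_zero(self):
        ds = _sine_epochs(10.0)
        ds.data[:] = 0.0
        out = ed.bandpass_filter(ds)
        assert np.allclose(out.data, 0.0)

    def test_band_above_nyquist_rejected(self):
        ds = _sine_epochs(10.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ed.bandpass_filter(ds, 1.0, 300.0)

    def test_dimensions_unchanged(self, null_dataset):
        out = ed.bandpass_filter(null_dataset)
        assert out.data.shape == null_dataset.data.shape


def _ramp_recording(fs: float = 500.0, n: int = 4000, n_ch: int = 3):
    data = np.arange(n, dtype=float)[None, :] * np.ones((n_ch, 1))
    data += 1000.0 * np.arange(n_ch)[:, None]
    return ed.ContinuousRecording(
        data=data,
        sampling_rate=fs,
        channel_names=[f"ch{i}" for i in range(n_ch)],
        events=[(1000, "S1"), (2000, "S2"), (3000, "S1")],
    )


class TestEpoch:
    def test_epoch_length_is_one_second(self):
        ds = ed.epoch(_ramp_recording(), (-300.0, 700.0))
        assert ds.n_samples == 500  # 1 s at 500 Hz
        assert ds.n_trials == 3
        assert ds.times[0] == -300.0

    def test_epochs_equal_continuous_slices(self):
        rec = _ramp_recording()
        ds = ed.epoch(rec, (-300.0, 700.0))
        for k, (sample, _code) in enumerate(rec.events):
            lo = sample - 150  # 300 ms pre-stimulus at 500 Hz
            assert np.array_equal(ds.data[k], rec.data[:, lo : lo + 500])

    def test_event_at_recording_edge_skipped(self):
        rec = _ramp_recording()
        rec.events.insert(0, (0, "S1"))
        with pytest.warns(UserWarning, match="skipped"):
            ds = ed.epoch(rec, (-300.0, 700.0))
        assert ds.n_trials == 3

    def test_label_mapping_filters_events(self):
        rec = _ramp_recording()
        ds = ed.epoch(rec, (-100.0, 100.0), label_for={"S1": "animal"})
        assert ds.n_trials == 2
        assert set(ds.labels) == {"animal"}


class TestRejectArtifacts:
    def _flat(self, n_trials=4, n_ch=2, n_samp=50):
        data = np.zeros((n_trials, n_ch, n_samp))
        return ed.EpochedDataset(
            data=data,
            times=np.arange(n_samp) * 2.0,
            labels=np.array(["a", "b"] * (n_trials // 2)),
            exemplar_ids=np.array(["e"] * n_trials),
            sampling_rate=500.0,
        )

    def test_range_over_threshold_rejected(self):
        ds = self._flat()
        ds.data[1, 0, 10] = 80.0
        ds.data[1, 0, 20] = -120.0  # range 200 > 150
        out = ed.reject_artifacts(ds, 150.0)
        assert out.n_trials == 3
        assert out.rejected_mask.tolist() == [False, True, False, False]

    def test_range_at_threshold_retained(self):
        ds = self._flat()
        ds.data[2, 1, 5] = 75.0
        ds.data[2, 1, 6] = -75.0  # range exactly 150
        out = ed.reject_artifacts(ds, 150.0)
        assert out.n_trials == 4

    def test_all_rejected_raises(self):
        ds = self._flat()
        ds.data[:, 0, 0] = 200.0
        ds.data[:, 0, 1] = -200.0
        with pytest.raises(ValueError, match="all trials"):
            ed.reject_artifacts(ds, 150.0)

    def test_permutation_equivariance(self, null_dataset):
        """Shuffling trials then rejecting equals rejecting then shuffling."""
        ds = ed.inject_artifacts(null_dataset, 0.2, 300.0, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_trials)
        a = ed.reject_artifacts(ds.select(perm), 150.0)
        b = ed.reject_artifacts(ds, 150.0)
        kept_orig = np.flatnonzero(~b.rejected_mask)
        kept_perm = perm[~a.rejected_mask]
        assert sorted(kept_perm) == sorted(kept_orig)

    def test_symmetric_injection_keeps_balance(self):
        """Random artifact injection on balanced data leaves the class
        imbalance within 1.5% on average (matching typical ERP rejection)."""
        imbalances = []
        for seed in range(5):
            ds = ed.generate_dataset(
                ed.SimulationConfig(
                    n_channels=10,
                    epoch_window=(-20.0, 80.0),
                    n_trials_per_exemplar=80,
                    exemplars=ed.default_exemplars(4),
                    seed=700 + seed,
                )
            )
            ds = ed.inject_artifacts(ds, 0.05, 300.0, seed=seed)
            kept = ed.reject_artifacts(ds, 150.0)
            imbalances.append(kept.class_balance())
        assert np.mean(imbalances) <= 0.015


class TestFeatures:
    def test_full_interval_feature_count(self):
        """60 channels x 350 samples (0-700 ms at 2 ms) = 21 000 features."""
        data = np.random.default_rng(0).standard_normal((2, 60, 500))
        ds = ed.EpochedDataset(
            data=data,
            times=-300.0 + 2.0 * np.arange(500),
            labels=np.array(["a", "b"]),
            exemplar_ids=np.array(["a0", "b0"]),
            sampling_rate=500.0,
        )
        fm = ed.extract_features(ds, (0.0, 700.0))
        assert fm.X.shape == (2, 21000)
        fm40 = ed.extract_features(ds, (100.0, 140.0))
        assert fm40.X.shape == (2, 1200)  # 60 x 20

    def test_feature_order_round_trip(self, null_dataset):
        """feature_index reconstructs the original epoch slice (channel-major)."""
        fm = ed.extract_features(null_dataset, (0.0, 40.0))
        grid = fm.feature_index.to_grid(fm.X[3])
        tsel = (null_dataset.times >= 0.0) & (null_dataset.times < 40.0)
        assert np.array_equal(grid, null_dataset.data[3][:, tsel])
        assert np.array_equal(fm.feature_index.from_grid(grid), fm.X[3])

    def test_empty_interval_rejected(self, null_dataset):
        with pytest.raises(ValueError):
            ed.extract_features(null_dataset, (40.0, 40.0))

    def test_interval_outside_epoch_rejected(self, null_dataset):
        with pytest.raises(ValueError, match="outside"):
            ed.extract_features(null_dataset, (0.0, 500.0))


class TestStandardize:
    def test_columns_are_zero_mean_unit_sd(self, null_dataset):
        fm = ed.standardize(ed.extract_features(null_dataset, (0.0, 80.0)))
        assert np.abs(fm.X.mean(axis=0)).max() < 1e-8
        assert np.abs(fm.X.std(axis=0) - 1.0).max() < 1e-8

    def test_stored_transform_reproduces_training_matrix(self, null_dataset):
        fm = ed.extract_features(null_dataset, (0.0, 80.0))
        scaler = ed.Standardizer().fit(fm)
        once = scaler.transform(fm)
        again = scaler.transform(fm)
        assert np.array_equal(once.X, again.X)

    def test_heldout_uses_training_statistics(self, null_dataset):
        """Transforming held-out trials with training stats differs from
        z-scoring them by their own stats (leakage guard)."""
        fm = ed.extract_features(null_dataset, (0.0, 80.0))
        train = FeatureMatrix(
            X=fm.X[:60], y=fm.y[:60], feature_index=fm.feature_index
        )
        test = FeatureMatrix(
            X=fm.X[60:], y=fm.y[60:], feature_index=fm.feature_index
        )
        via_train = ed.Standardizer().fit(train).transform(test)
        via_self = ed.Standardizer().fit(test).transform(test)
        assert not np.allclose(via_train.X, via_self.X)

    def test_zero_variance_feature_identified(self, null_dataset):
        fm = ed.extract_features(null_dataset, (0.0, 80.0))
        fm.X[:, 1] = 7.0  # channel 0, second time sample
        with pytest.raises(ValueError, match="channel 0"):
            ed.standardize(fm)


def test_filter_epoch_commutation_on_interior_samples():
    """Filtering the continuous signal then epoching matches epoching then
    filtering on the central half of the epoch, within 10% of signal RMS,
    for in-band content and a 5 Hz high-pass edge.  (A 1 Hz edge has an
    impulse response comparable to the epoch length, so per-epoch filtering
    is documented as approximate.)"""
    rng = np.random.default_rng(0)
    fs, n = 500.0, 5000
    tt = np.arange(n) / fs
    data = np.zeros((2, n))
    for ch in range(2):
        for f in (8.0, 13.0, 21.0):
            data[ch] += np.sin(2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi))
    rec = ed.ContinuousRecording(
        data=data,
        sampling_rate=fs,
        channel_names=["a", "b"],
        events=[(1500, "S1"), (2500, "S1")],
    )
    a = ed.epoch(filter_continuous(rec, 5.0, 30.0), (-300.0, 700.0))
    b = ed.bandpass_filter(ed.epoch(rec, (-300.0, 700.0)), 5.0, 30.0)
    rms = np.sqrt((a.data**2).mean())
    central = slice(125, 375)
    assert np.abs(a.data - b.data)[:, :, central].max() < 0.1 * rms
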