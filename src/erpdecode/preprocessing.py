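"""Preprocessing chain: band-pass filtering, epoching, artifact rejection,
feature extraction and leakage-safe standardization.

The chain mirrors standard single-trial ERP practice: zero-phase 1-30 Hz
band-pass, 1-s epochs from -300 ms before onset, rejection of trials whose
within-epoch peak-to-peak range on any channel exceeds 150 µV, extraction of
the post-stimulus channel x time voltage samples as features, and per-feature
z-scoring with statistics estimated on training trials only.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import signal

from .datasets import ContinuousRecording, EpochedDataset, FeatureIndex, FeatureMatrix

__all__ = [
    "bandpass_filter",
    "epoch",
    "reject_artifacts",
    "extract_features",
    "Standardizer",
    "standardize",
]

#: IIR filter order (Butterworth, applied forward and backward).
FILTER_ORDER = 4


def _design_bandpass(low: float, high: float, sampling_rate: float):
    nyquist = sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("require 0 < low < high")
    if high >= nyquist:
        raise ValueError(
            f"upper band edge {high} Hz must lie below the Nyquist frequency "
            f"{nyquist} Hz"
        )
    return signal.butter(
        FILTER_ORDER, [low, high], btype="bandpass", fs=sampling_rate, output="sos"
    )


def bandpass_filter(epochs: EpochedDataset, low: float = 1.0, high: float = 30.0) -> EpochedDataset:
    """Zero-phase Butterworth band-pass applied per trial and channel."""
    sos = _design_bandpass(low, high, epochs.sampling_rate)
    filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=np.ascontiguousarray(filtered))


def filter_continuous(
    recording: ContinuousRecording, low: float = 1.0, high: float = 30.0
) -> ContinuousRecording:
    """Zero-phase band-pass on a continuous recording (applied per channel)."""
    sos = _design_bandpass(low, high, recording.sampling_rate)
    data = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return ContinuousRecording(
        data=np.ascontiguousarray(data),
        sampling_rate=recording.sampling_rate,
        channel_names=list(recording.channel_names),
        events=list(recording.events),
    )


def epoch(
    recording: ContinuousRecording,
    window: tuple[float, float] = (-300.0, 700.0),
    label_for: dict[str, str] | None = None,
) -> EpochedDataset:
    """Cut one epoch per event from a continuous recording.

    ``window`` is in ms relative to event onset, half-open.  Events whose
    window falls outside the recording are skipped with a warning.  When
    ``label_for`` is given, event codes are mapped to category labels and
    unmapped events are ignored; otherwise the event code doubles as label
    and exemplar id.
    """
    fs = recording.sampling_rate
    start_samp = int(round(window[0] * fs / 1000.0))
    n_samples = int(round((window[1] - window[0]) * fs / 1000.0))
    if n_samples <= 0:
        raise ValueError("empty epoch window")
    times = window[0] + 1000.0 / fs * np.arange(n_samples)

    blocks, labels, exemplars = [], [], []
    for sample, code in recording.events:
        if label_for is not None and code not in label_for:
            continue
        lo = sample + start_samp
        hi = lo + n_samples
        if lo < 0 or hi > recording.n_samples:
            warnings.warn(
                f"event at sample {sample} too close to the recording edge; skipped",
                stacklevel=2,
            )
            continue
        blocks.append(recording.data[:, lo:hi])
        labels.append(label_for[code] if label_for is not None else code)
        exemplars.append(code)
    if not blocks:
        raise ValueError("no events produced valid epochs")
    return EpochedDataset(
        data=np.stack(blocks),
        times=times,
        labels=np.asarray(labels, dtype=str),
        exemplar_ids=np.asarray(exemplars, dtype=str),
        sampling_rate=fs,
    )


def peak_to_peak(epochs: EpochedDataset) -> np.ndarray:
    """Within-epoch per-channel peak-to-peak range, shape (trials, channels)."""
    return epochs.data.max(axis=-1) - epochs.data.min(axis=-1)


def reject_artifacts(epochs: EpochedDataset, threshold: float = 150.0) -> EpochedDataset:
    """Drop trials whose peak-to-peak range on any channel exceeds ``threshold`` µV.

    The rejection decision is recorded in ``rejected_mask`` (aligned with the
    *input* trial order); the surviving trials are returned.
    """
    if threshold <= 0:
        raise ValueError("rejection threshold must be positive")
    ranges = peak_to_peak(epochs)
    rejected = (ranges > threshold).any(axis=1)
    if rejected.all():
        raise ValueError("all trials rejected; no data left for analysis")
    kept = epochs.select(np.flatnonzero(~rejected))
    kept.rejected_mask = rejected
    return kept


def extract_features(
    epochs: EpochedDataset, interval: tuple[float, float] = (0.0, 700.0)
) -> FeatureMatrix:
    """Flatten the voltages in ``interval`` (ms, half-open) into trials x features.

    Feature order is channel-major, time-minor; ``feature_index`` records the
    (channel, time) identity of every column.  Labels are coded 0/1 in sorted
    category order.
    """
    lo, hi = interval
    sel = (epochs.times >= lo) & (epochs.times < hi)
    if not sel.any():
        raise ValueError(f"interval {interval} contains no samples")
    if lo < epochs.times[0] or hi > epochs.times[-1] + 1000.0 / epochs.sampling_rate:
        raise ValueError(f"interval {interval} outside the epoch window")
    sub = epochs.data[:, :, sel]  # (trials, channels, t)
    n_trials = sub.shape[0]
    X = sub.reshape(n_trials, -1)
    classes = np.unique(epochs.labels)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    y = (epochs.labels == classes[1]).astype(int)
    index = FeatureIndex(
        channels=np.arange(epochs.n_channels), times_ms=epochs.times[sel]
    )
    return FeatureMatrix(X=X, y=y, feature_index=index, classes=classes)


class Standardizer:
    """Per-feature z-scoring with train-set statistics.

    Statistics are estimated once with :meth:`fit` (training trials only) and
    re-applied to held-out trials with :meth:`transform`, so no test-trial
    information leaks into the scaling.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, features: FeatureMatrix) -> "Standardizer":
        X = features.X
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            f = int(bad[0])
            idx = features.feature_index
            ch = idx.feature_channel()[f]
            t = idx.feature_time()[f]
            raise ValueError(
                f"zero-variance feature at channel {ch}, {t:g} ms; cannot standardize"
            )
        self.mean_, self.sd_ = mean, sd
        return self

    def transform(self, features: FeatureMatrix) -> FeatureMatrix:
        if self.mean_ is None:
            raise ValueError("Standardizer must be fitted first")
        Z = (features.X - self.mean_) / self.sd_
        return FeatureMatrix(
            X=Z,
            y=features.y,
            feature_index=features.feature_index,
            classes=features.classes,
            mean_=self.mean_,
            sd_=self.sd_,
        )

    def fit_transform(self, features: FeatureMatrix) -> FeatureMatrix:
        return self.fit(features).transform(features)


def standardize(features: FeatureMatrix) -> FeatureMatrix:
    """Z-score every feature column across trials (stats stored on the result)."""
    return Standardizer().fit_transform(features)
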