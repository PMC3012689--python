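"""In-memory containers for epoched EEG, continuous recordings and feature matrices.

Conventions used throughout the package:

* voltages are in microvolts (µV);
* the epoch time axis is in milliseconds relative to stimulus onset, with
  sample timestamps at ``start, start + dt, ..., end - dt`` (half-open
  window) where ``dt = 1000 / sampling_rate``;
* features are ordered channel-major, time-minor, and :class:`FeatureIndex`
  is the single source of truth for the feature -> (channel, time) bijection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContinuousRecording",
    "EpochedDataset",
    "FeatureIndex",
    "FeatureMatrix",
    "epoch_times",
]


def epoch_times(window_ms: tuple[float, float], sampling_rate: float) -> np.ndarray:
    """Sample timestamps (ms) for a half-open epoch window at a given rate."""
    start, end = window_ms
    if not end > start:
        raise ValueError(f"epoch window start must precede end, got {window_ms}")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    dt = 1000.0 / sampling_rate
    n = int(round((end - start) / dt))
    return start + dt * np.arange(n)


@dataclass
class ContinuousRecording:
    """A continuous multichannel EEG recording with stimulus events.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)`` in µV.
    sampling_rate:
        Sampling rate in Hz.
    channel_names:
        One label per channel.
    events:
        Sequence of ``(sample_index, event_code)`` pairs.
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("continuous data must be (n_channels, n_samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")
        n = self.data.shape[1]
        for idx, _code in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event sample index {idx} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedDataset:
    """Epoched trials with per-trial category labels and exemplar identity.

    ``data`` has shape ``(n_trials, n_channels, n_samples)`` in µV;
    ``times`` is the shared epoch time axis in ms relative to onset.
    ``ground_truth_mask`` (simulated data only) marks the channel x time
    cells carrying the category-general effect.
    """

    data: np.ndarray
    times: np.ndarray
    labels: np.ndarray
    exemplar_ids: np.ndarray
    sampling_rate: float
    modality: str = ""
    rejected_mask: np.ndarray | None = None
    artifact_mask: np.ndarray | None = None
    ground_truth_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels)
        self.exemplar_ids = np.asarray(self.exemplar_ids)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be (n_trials, n_channels, n_samples)")
        n_trials, _, n_samples = self.data.shape
        if self.times.shape != (n_samples,):
            raise ValueError("time axis length must match the sample dimension")
        if self.labels.shape != (n_trials,):
            raise ValueError("one label per trial required")
        if self.exemplar_ids.shape != (n_trials,):
            raise ValueError("one exemplar id per trial required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        # time axis spacing must match the sampling rate
        if n_samples > 1:
            dt = 1000.0 / self.sampling_rate
            if not np.allclose(np.diff(self.times), dt, atol=1e-6):
                raise ValueError("time axis spacing inconsistent with sampling rate")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(n_trials, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def categories(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_balance(self) -> float:
        """Absolute class-count difference as a fraction of trial count."""
        cats, counts = np.unique(self.labels, return_counts=True)
        if len(cats) != 2:
            raise ValueError("class balance is defined for two categories")
        return abs(int(counts[0]) - int(counts[1])) / self.n_trials

    def select(self, idx: np.ndarray) -> "EpochedDataset":
        """A new dataset restricted to the given trial indices."""
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[idx],
            labels=self.labels[idx],
            exemplar_ids=self.exemplar_ids[idx],
            artifact_mask=self.artifact_mask[idx],
            rejected_mask=None,
        )


class FeatureIndex:
    """Bijection between flat feature indices and (channel, time) cells.

    Channel-major, time-minor: feature ``f`` maps to channel ``f // n_times``
    and time index ``f % n_times``.
    """

    def __init__(self, channels: np.ndarray, times_ms: np.ndarray) -> None:
        self.channels = np.asarray(channels, dtype=int)
        self.times_ms = np.asarray(times_ms, dtype=float)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_times(self) -> int:
        return len(self.times_ms)

    @property
    def n_features(self) -> int:
        return self.n_channels * self.n_times

    def feature_channel(self) -> np.ndarray:
        """Channel index of every feature, length ``n_features``."""
        return np.repeat(self.channels, self.n_times)

    def feature_time(self) -> np.ndarray:
        """Timestamp (ms) of every feature, length ``n_features``."""
        return np.tile(self.times_ms, self.n_channels)

    def to_grid(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-feature vector onto the (channels, times) grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {values.shape[-1]}"
            )
        return values.reshape(values.shape[:-1] + (self.n_channels, self.n_times))

    def from_grid(self, grid: np.ndarray) -> np.ndarray:
        """Flatten a (channels, times) grid into feature order."""
        grid = np.asarray(grid)
        if grid.shape[-2:] != (self.n_channels, self.n_times):
            raise ValueError("grid shape does not match feature index")
        return grid.reshape(grid.shape[:-2] + (self.n_features,))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FeatureIndex)
            and np.array_equal(self.channels, other.channels)
            and np.array_equal(self.times_ms, other.times_ms)
        )


@dataclass
class FeatureMatrix:
    """Trials x features design matrix with binary labels.

    ``y`` holds 0/1 codes; ``classes`` records the original category labels
    in code order so predictions can be mapped back.
    """

    X: np.ndarray
    y: np.ndarray
    feature_index: FeatureIndex
    classes: np.ndarray | None = None
    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (trials x features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("one label per trial required")
        if self.X.shape[1] != self.feature_index.n_features:
            raise ValueError("feature count does not match feature_index")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def is_standardized(self) -> bool:
        return self.mean_ is not None
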