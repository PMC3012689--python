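"""Synthetic epoched-ERP generator with known discriminative structure.

The generator emulates a two-category object-recognition EEG study: a small
set of exemplars (e.g. 2 categories x 4 exemplars), each repeated many times,
recorded on a multichannel montage at 500 Hz with 1-s epochs starting 300 ms
before stimulus onset.  Every trial is the sum of

* a class-independent ERP-like background (smooth half-sine components with
  P1/N1/late-wave latencies and a fixed random topography),
* optional category-general effects (half-sine bumps added with opposite
  sign to the two categories, so the class-mean difference at the bump peak
  equals the stated amplitude),
* optional exemplar-specific effects (per-exemplar random-sign bumps that
  make exemplars identifiable without carrying category information),
* spatially mixed AR(1) noise, and
* optional high-amplitude transient artifacts.

All randomness flows from a single master seed; per-trial noise streams are
spawned deterministically so subsetting trials is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import EpochedDataset, epoch_times

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "SimulationConfig",
    "default_exemplars",
    "generate_dataset",
    "inject_artifacts",
]


def default_exemplars(
    n_per_category: int = 4, categories: tuple[str, str] = ("animal", "tool")
) -> list[tuple[str, str]]:
    """``(exemplar_id, category)`` pairs for a balanced two-category design."""
    out = []
    for cat in categories:
        for i in range(n_per_category):
            out.append((f"{cat}_{i}", cat))
    return out


@dataclass
class EffectSpec:
    """A spatiotemporally localized discriminative effect.

    ``scope='category-general'`` adds the bump with sign +amplitude/2 to one
    category and -amplitude/2 to the other on the listed channels, so the
    between-class mean difference at the bump peak equals ``amplitude``.
    ``scope='exemplar-specific'`` draws an independent random sign per
    (exemplar, channel): exemplars become separable but the category means
    stay equal in expectation.
    """

    channels: tuple[int, ...]
    time_window: tuple[float, float]  # ms, half-open
    amplitude: float  # µV
    polarity: int = 1
    scope: str = "category-general"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("effect amplitude must be non-negative")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        if self.scope not in ("category-general", "exemplar-specific"):
            raise ValueError(f"unknown effect scope {self.scope!r}")
        if not self.time_window[1] > self.time_window[0]:
            raise ValueError("effect time window start must precede end")


@dataclass
class NoiseSpec:
    """Background-noise model: per-channel AR(1) plus spatial mixing.

    ``background_sd`` is the marginal per-sample noise SD in µV;
    ``temporal_ar_coefficient`` the AR(1) coefficient; channels are averaged
    with ``spatial_mixing_neighbors`` index-adjacent neighbours on each side
    to induce inter-channel correlation. ``erp_background_amplitude`` scales
    the shared class-independent ERP waveform.
    """

    background_sd: float = 8.0
    temporal_ar_coefficient: float = 0.9
    spatial_mixing_neighbors: int = 2
    erp_background_amplitude: float = 6.0

    def __post_init__(self) -> None:
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")
        if not -1 < self.temporal_ar_coefficient < 1:
            raise ValueError("AR coefficient must lie in (-1, 1)")
        if self.spatial_mixing_neighbors < 0:
            raise ValueError("spatial_mixing_neighbors must be >= 0")


@dataclass
class SimulationConfig:
    """Full description of one simulated session."""

    n_channels: int = 60
    sampling_rate: float = 500.0
    epoch_window: tuple[float, float] = (-300.0, 700.0)
    n_trials_per_exemplar: int = 80
    exemplars: list[tuple[str, str]] = field(default_factory=default_exemplars)
    category_effect: list[EffectSpec] = field(default_factory=list)
    exemplar_effect: list[EffectSpec] = field(default_factory=list)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    artifact_rate: float = 0.0
    artifact_amplitude: float = 200.0
    modality: str = "simulated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.epoch_window[1] > self.epoch_window[0]:
            raise ValueError("epoch window start must precede end")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")
        if self.n_trials_per_exemplar <= 0:
            raise ValueError("n_trials_per_exemplar must be positive")
        if not self.exemplars:
            raise ValueError("at least one exemplar required")
        for eff in list(self.category_effect) + list(self.exemplar_effect):
            lo, hi = eff.time_window
            if lo < self.epoch_window[0] or hi > self.epoch_window[1]:
                raise ValueError(
                    f"effect window {eff.time_window} outside epoch window "
                    f"{self.epoch_window}"
                )
            for ch in eff.channels:
                if not 0 <= ch < self.n_channels:
                    raise ValueError(f"effect channel {ch} out of range")

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, cat in self.exemplars:
            seen.setdefault(cat, None)
        return list(seen)


def _half_sine(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Half-sine bump supported on [start, end): 0 at the edges, 1 at centre."""
    lo, hi = window
    out = np.zeros_like(times)
    inside = (times >= lo) & (times < hi)
    out[inside] = np.sin(math.pi * (times[inside] - lo) / (hi - lo))
    return out


def _erp_background(
    times: np.ndarray, n_channels: int, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Shared class-independent ERP: P1-, N1- and late-wave-like components.

    Returns a (n_channels, n_samples) waveform; topographies are smooth random
    channel weights fixed per dataset.
    """
    components = [  # (window ms, relative amplitude)
        ((70.0, 150.0), 0.7),   # P1-like
        ((110.0, 220.0), -1.0),  # N1-like
        ((280.0, 550.0), 0.5),   # late wave
    ]
    wave = np.zeros((n_channels, len(times)))
    for window, rel in components:
        topo = rng.normal(0.6, 0.3, size=n_channels)
        wave += amplitude * rel * np.outer(topo, _half_sine(times, window))
    return wave


def _ar1_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, sd: float, phi: float
) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd`` per channel."""
    from scipy.signal import lfilter

    innov_sd = sd * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=(n_channels, n_samples))
    eps[:, 0] = rng.normal(0.0, sd, size=n_channels)  # stationary start
    return lfilter([1.0], [1.0, -phi], eps, axis=1)


def _spatial_mix(noise: np.ndarray, k: int) -> np.ndarray:
    """Average each channel with its k index-neighbours on either side."""
    if k == 0:
        return noise
    n_channels = noise.shape[0]
    mixed = np.zeros_like(noise)
    counts = np.zeros(n_channels)
    for offset in range(-k, k + 1):
        lo = max(0, -offset)
        hi = min(n_channels, n_channels - offset)
        mixed[lo:hi] += noise[lo + offset : hi + offset]
        counts[lo:hi] += 1
    mixed /= counts[:, None]
    # restore the marginal SD removed by averaging (approximate: white across
    # channels would shrink by sqrt(count))
    mixed *= np.sqrt(counts)[:, None]
    return mixed


def generate_dataset(config: SimulationConfig) -> EpochedDataset:
    """Simulate one epoched session from a :class:`SimulationConfig`.

    Deterministic given ``config.seed``.  The returned dataset carries a
    ``ground_truth_mask`` over the (channels, samples) grid marking exactly
    the cells touched by the category-general effects.
    """
    times = epoch_times(config.epoch_window, config.sampling_rate)
    n_samples = len(times)
    n_channels = config.n_channels
    exemplars = config.exemplars
    n_trials = config.n_trials_per_exemplar * len(exemplars)

    ss = np.random.SeedSequence(config.seed)
    dataset_ss, trial_parent = ss.spawn(2)
    dataset_rng = np.random.default_rng(dataset_ss)
    trial_streams = trial_parent.spawn(n_trials)

    background = _erp_background(
        times, n_channels, config.noise.erp_background_amplitude, dataset_rng
    )

    categories = config.categories
    if len(categories) != 2:
        raise ValueError("generator requires exactly two categories")
    cat_sign = {categories[0]: -1.0, categories[1]: 1.0}

    # category-general templates and the ground-truth mask
    cat_template = np.zeros((n_channels, n_samples))
    mask = np.zeros((n_channels, n_samples), dtype=bool)
    for eff in config.category_effect:
        bump = _half_sine(times, eff.time_window)
        for ch in eff.channels:
            cat_template[ch] += eff.polarity * eff.amplitude * 0.5 * bump
            mask[ch] |= bump > 0

    # exemplar-specific templates: each exemplar gets a signature over the
    # (channel x lobe) coefficient space of the effect window, where the
    # window is tiled by three disjoint half-sine lobes.  Signatures are
    # drawn MUTUALLY ORTHOGONAL (QR of a random Gaussian matrix), so they
    # make exemplars individually recognizable within a session while
    # carrying, by construction, no category-level structure that could
    # generalize to a held-out exemplar.
    ex_templates = {ex_id: np.zeros((n_channels, n_samples)) for ex_id, _ in exemplars}
    for eff in config.exemplar_effect:
        lo, hi = eff.time_window
        edges = np.linspace(lo, hi, 4)
        lobes = [_half_sine(times, (edges[k], edges[k + 1])) for k in range(3)]
        d = 3 * len(eff.channels)
        if d < len(exemplars):
            raise ValueError(
                "exemplar-specific effect needs 3 x n_channels >= n_exemplars "
                "for orthogonal signatures"
            )
        raw = dataset_rng.standard_normal((d, len(exemplars)))
        q, _ = np.linalg.qr(raw)  # orthonormal signature per exemplar
        coeffs = eff.polarity * eff.amplitude * math.sqrt(d) * q.T  # (n_ex, d)
        for e, (ex_id, _cat) in enumerate(exemplars):
            c = coeffs[e].reshape(len(eff.channels), 3)
            for i, ch in enumerate(eff.channels):
                for k, lobe in enumerate(lobes):
                    ex_templates[ex_id][ch] += c[i, k] * lobe

    labels = np.empty(n_trials, dtype=object)
    exemplar_ids = np.empty(n_trials, dtype=object)
    data = np.empty((n_trials, n_channels, n_samples))
    phi = config.noise.temporal_ar_coefficient
    sd = config.noise.background_sd
    k_mix = config.noise.spatial_mixing_neighbors
    t = 0
    for ex_id, cat in exemplars:
        for _rep in range(config.n_trials_per_exemplar):
            rng = np.random.default_rng(trial_streams[t])
            noise = _spatial_mix(
                _ar1_noise(rng, n_channels, n_samples, sd, phi), k_mix
            )
            data[t] = (
                background
                + cat_sign[cat] * cat_template
                + ex_templates[ex_id]
                + noise
            )
            labels[t] = cat
            exemplar_ids[t] = ex_id
            t += 1

    labels = labels.astype(str)
    exemplar_ids = exemplar_ids.astype(str)
    dataset = EpochedDataset(
        data=data,
        times=times,
        labels=labels,
        exemplar_ids=exemplar_ids,
        sampling_rate=config.sampling_rate,
        modality=config.modality,
        ground_truth_mask=mask,
    )
    if config.artifact_rate > 0:
        artifact_seed = int(dataset_rng.integers(0, 2**31 - 1))
        dataset = inject_artifacts(
            dataset, config.artifact_rate, config.artifact_amplitude, artifact_seed
        )
    return dataset


def inject_artifacts(
    dataset: EpochedDataset, rate: float, amplitude: float, seed: int
) -> EpochedDataset:
    """Add a transient high-amplitude deflection to a random subset of trials.

    ``floor(rate * n_trials)`` trials (chosen without replacement) receive a
    one-sided half-sine bump of peak ``amplitude`` µV on one random channel,
    spanning the middle third of the epoch.  Affected trials are flagged in
    ``artifact_mask``.  The input dataset is not modified.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("artifact rate must lie in [0, 1]")
    if amplitude <= 0:
        raise ValueError("artifact amplitude must be positive")
    n_flag = int(rate * dataset.n_trials)
    data = dataset.data.copy()
    artifact_mask = dataset.artifact_mask.copy()
    if n_flag > 0:
        rng = np.random.default_rng(seed)
        trials = rng.choice(dataset.n_trials, size=n_flag, replace=False)
        t0 = dataset.times[0]
        t1 = dataset.times[-1]
        span = t1 - t0
        window = (t0 + span / 3.0, t0 + 2.0 * span / 3.0)
        bump = _half_sine(dataset.times, window)
        for tr in trials:
            ch = int(rng.integers(dataset.n_channels))
            data[tr, ch] += amplitude * bump
            artifact_mask[tr] = True
    return replace(dataset, data=data, artifact_mask=artifact_mask, rejected_mask=None)
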