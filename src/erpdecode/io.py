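"""File formats: the internal HDF5 container, BrainVision input, tabular
report export and the run configuration.

The internal container is a single HDF5 file holding the arrays of one
object (dataset, feature matrix, posterior fit or evaluation report) plus a
JSON metadata block and a schema version; round-trips are lossless.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, fields

import h5py
import numpy as np
import pandas as pd
import yaml

from .datasets import ContinuousRecording, EpochedDataset, FeatureIndex, FeatureMatrix
from .evaluation import EvaluationReport
from .model import PosteriorFit

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "read_brainvision",
    "write_dataset",
    "read_dataset",
    "write_features",
    "read_features",
    "write_fit",
    "read_fit",
    "write_report",
    "read_report",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------- container

def _open_write(path, kind: str) -> h5py.File:
    f = h5py.File(path, "w")
    f.attrs["schema_version"] = SCHEMA_VERSION
    f.attrs["kind"] = kind
    return f


def _open_read(path, kind: str) -> h5py.File:
    f = h5py.File(path, "r")
    version = int(f.attrs.get("schema_version", -1))
    if version != SCHEMA_VERSION:
        f.close()
        raise ValueError(
            f"container schema version {version} not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    found = f.attrs.get("kind", "")
    if found != kind:
        f.close()
        raise ValueError(f"container holds {found!r}, expected {kind!r}")
    return f


def _write_strings(group, name, values) -> None:
    group.create_dataset(name, data=np.asarray(values, dtype=object),
                         dtype=h5py.string_dtype())


def _read_strings(group, name) -> np.ndarray:
    return np.asarray([s.decode() if isinstance(s, bytes) else s
                       for s in group[name][()]])


def write_dataset(path, dataset: EpochedDataset) -> None:
    with _open_write(path, "epoched_dataset") as f:
        f.create_dataset("data", data=dataset.data)
        f.create_dataset("times", data=dataset.times)
        _write_strings(f, "labels", dataset.labels)
        _write_strings(f, "exemplar_ids", dataset.exemplar_ids)
        f.create_dataset("artifact_mask", data=dataset.artifact_mask)
        f.attrs["sampling_rate"] = dataset.sampling_rate
        f.attrs["modality"] = dataset.modality
        if dataset.rejected_mask is not None:
            f.create_dataset("rejected_mask", data=dataset.rejected_mask)
        if dataset.ground_truth_mask is not None:
            f.create_dataset("ground_truth_mask", data=dataset.ground_truth_mask)


def read_dataset(path) -> EpochedDataset:
    with _open_read(path, "epoched_dataset") as f:
        if "labels" not in f:
            raise ValueError("container is missing per-trial labels")
        return EpochedDataset(
            data=f["data"][()],
            times=f["times"][()],
            labels=_read_strings(f, "labels"),
            exemplar_ids=_read_strings(f, "exemplar_ids"),
            sampling_rate=float(f.attrs["sampling_rate"]),
            modality=str(f.attrs["modality"]),
            artifact_mask=f["artifact_mask"][()],
            rejected_mask=f["rejected_mask"][()] if "rejected_mask" in f else None,
            ground_truth_mask=(
                f["ground_truth_mask"][()] if "ground_truth_mask" in f else None
            ),
        )


def write_features(path, fm: FeatureMatrix) -> None:
    with _open_write(path, "feature_matrix") as f:
        f.create_dataset("X", data=fm.X)
        f.create_dataset("y", data=np.asarray(fm.y, dtype=int))
        f.create_dataset("channels", data=fm.feature_index.channels)
        f.create_dataset("times_ms", data=fm.feature_index.times_ms)
        if fm.classes is not None:
            _write_strings(f, "classes", fm.classes)
        if fm.mean_ is not None:
            f.create_dataset("mean", data=fm.mean_)
            f.create_dataset("sd", data=fm.sd_)


def read_features(path) -> FeatureMatrix:
    with _open_read(path, "feature_matrix") as f:
        if "y" not in f:
            raise ValueError("container is missing labels")
        return FeatureMatrix(
            X=f["X"][()],
            y=f["y"][()],
            feature_index=FeatureIndex(f["channels"][()], f["times_ms"][()]),
            classes=_read_strings(f, "classes") if "classes" in f else None,
            mean_=f["mean"][()] if "mean" in f else None,
            sd_=f["sd"][()] if "sd" in f else None,
        )


def write_fit(path, fit: PosteriorFit) -> None:
    with _open_write(path, "posterior_fit") as f:
        for name in ("coef_mean", "coef_var", "aux_variance"):
            f.create_dataset(name, data=getattr(fit, name))
        f.attrs["bias_mean"] = fit.bias_mean
        f.attrs["bias_var"] = fit.bias_var
        f.attrs["converged"] = fit.converged
        f.attrs["n_sweeps"] = fit.n_sweeps
        f.attrs["max_residual"] = fit.max_residual
        if fit.classes is not None:
            _write_strings(f, "classes", fit.classes)


def read_fit(path) -> PosteriorFit:
    """Read a posterior fit (summary arrays; predictive internals not stored)."""
    with _open_read(path, "posterior_fit") as f:
        return PosteriorFit(
            coef_mean=f["coef_mean"][()],
            coef_var=f["coef_var"][()],
            bias_mean=float(f.attrs["bias_mean"]),
            bias_var=float(f.attrs["bias_var"]),
            aux_variance=f["aux_variance"][()],
            converged=bool(f.attrs["converged"]),
            n_sweeps=int(f.attrs["n_sweeps"]),
            max_residual=float(f.attrs["max_residual"]),
            classes=_read_strings(f, "classes") if "classes" in f else None,
        )


def _write_frame(group, frame: pd.DataFrame) -> None:
    group.attrs["columns"] = list(frame.columns)
    for col in frame.columns:
        values = frame[col].to_numpy()
        if values.dtype == object or values.dtype.kind in "U":
            _write_strings(group, col, values.astype(str))
        else:
            group.create_dataset(col, data=values)


def _read_frame(group) -> pd.DataFrame:
    cols = list(group.attrs["columns"])
    data = {}
    for col in cols:
        ds = group[col]
        if h5py.check_string_dtype(ds.dtype):
            data[col] = _read_strings(group, col)
        else:
            data[col] = ds[()]
    return pd.DataFrame(data, columns=cols)


def write_report(path, report: EvaluationReport) -> None:
    with _open_write(path, "evaluation_report") as f:
        f.attrs["analysis"] = report.analysis
        f.attrs["accuracy"] = report.accuracy
        f.attrs["alpha"] = report.alpha
        f.attrs["bonferroni_m"] = report.bonferroni_m
        _write_frame(f.create_group("table"), report.table)
        _write_frame(f.create_group("predictions"), report.predictions)
        imp = f.create_group("importance")
        for name, m in report.importance.items():
            g = imp.create_group(name)
            g.create_dataset("values", data=m.values)
            g.create_dataset("channels", data=m.channels)
            g.create_dataset("times_ms", data=m.times_ms)
            g.attrs["normalized"] = m.normalized


def read_report(path) -> EvaluationReport:
    from .model import ImportanceMap

    with _open_read(path, "evaluation_report") as f:
        importance = {}
        for name, g in f["importance"].items():
            importance[name] = ImportanceMap(
                values=g["values"][()],
                channels=g["channels"][()],
                times_ms=g["times_ms"][()],
                normalized=bool(g.attrs["normalized"]),
            )
        return EvaluationReport(
            analysis=str(f.attrs["analysis"]),
            table=_read_frame(f["table"]),
            accuracy=float(f.attrs["accuracy"]),
            predictions=_read_frame(f["predictions"]),
            importance=importance,
            alpha=float(f.attrs["alpha"]),
            bonferroni_m=int(f.attrs["bonferroni_m"]),
        )


# ---------------------------------------------------------------- BrainVision

def read_brainvision(header_path) -> ContinuousRecording:
    """Read a BrainVision triplet (.vhdr/.vmrk/.eeg) as a ContinuousRecording.

    Uses MNE for the format's common dialect (INT_16 / IEEE_FLOAT_32,
    multiplexed).  Voltages are returned in µV; stimulus markers become
    ``(sample_index, description)`` events.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("BrainVision input requires the 'mne' package") from exc
    try:
        raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"could not parse BrainVision header {header_path}: {exc}")
    data = raw.get_data() * 1e6  # volts -> µV
    sfreq = float(raw.info["sfreq"])
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc.startswith("New Segment"):
            continue
        events.append((int(round(onset * sfreq)), str(desc)))
    return ContinuousRecording(
        data=data,
        sampling_rate=sfreq,
        channel_names=list(raw.ch_names),
        events=events,
    )


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """All stage parameters of one pipeline run, serializable to YAML.

    Unknown keys in a config file are rejected; ``provenance`` returns a
    content hash plus package version and timestamp for result files.
    """

    seed: int = 0
    filter_low: float = 1.0
    filter_high: float = 30.0
    reject_threshold: float = 150.0
    interval: tuple[float, float] = (0.0, 700.0)
    window_width: float = 40.0
    window_start: float = 0.0
    window_end: float = 640.0
    k_folds: int = 5
    coupling_strength: float = 100.0
    regularization: float = 1.0
    couple_channels: bool = False
    ep_damping: float = 0.5
    ep_tol: float = 1e-4
    ep_max_sweeps: int = 200
    alpha: float = 0.05
    bonferroni_m: int = 1
    # generator parameters
    n_channels: int = 60
    sampling_rate: float = 500.0
    epoch_start: float = -300.0
    epoch_end: float = 700.0
    n_trials_per_exemplar: int = 80
    n_exemplars_per_category: int = 4
    effect_amplitude: float = 0.0
    effect_channels: tuple[int, ...] = ()
    effect_window: tuple[float, float] = (100.0, 200.0)
    effect_scope: str = "category-general"
    noise_sd: float = 8.0
    noise_ar: float = 0.9
    noise_mix_neighbors: int = 2
    erp_background_amplitude: float = 6.0
    artifact_rate: float = 0.0
    artifact_amplitude: float = 200.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        tuple_fields = {"interval", "effect_window", "effect_channels"}
        kwargs = {
            k: tuple(v) if k in tuple_fields and v is not None else v
            for k, v in raw.items()
        }
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def provenance(self) -> dict:
        from . import __version__

        return {
            "config_hash": self.config_hash(),
            "package_version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "seed": self.seed,
        }
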