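"""The four decoding analyses and binomial significance testing.

* within-modality stratified k-fold cross-validation (default k = 5),
* sliding-window decoding (default 16 windows of 40 ms from 0 to 640 ms),
* unseen-exemplar generalization (leave-one-exemplar-out),
* transfer learning: one joint fit over several datasets whose auxiliary
  variables are coupled feature-by-feature through the multivariate Laplace
  prior, and
* an exact one-sided binomial test of classifier accuracy against the
  baseline that assigns every trial to the most prevalent class, with
  Bonferroni correction.

Fold standardization statistics are always computed on training trials only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from . import model as mdl
from .datasets import EpochedDataset, FeatureIndex, FeatureMatrix
from .model import EPOptions, ImportanceMap
from .precision import (
    CouplingSpec,
    build_precision,
    cross_dataset_pairs,
    spatial_pairs,
    temporal_pairs,
)
from .preprocessing import Standardizer, extract_features

__all__ = [
    "ModelSpec",
    "CVScheme",
    "EvaluationReport",
    "cross_validate",
    "sliding_window",
    "unseen_exemplar",
    "transfer_learning",
    "binomial_significance",
]


@dataclass
class ModelSpec:
    """Classifier configuration shared by all analyses.

    ``interval`` is the feature window in ms (half-open); coupling defaults
    follow the temporal-neighbour prior with c = 100, lambda = 1.
    """

    interval: tuple[float, float] = (0.0, 700.0)
    coupling_strength: float = 100.0
    regularization: float = 1.0
    couple_channels: bool = False
    ep: EPOptions = field(default_factory=EPOptions)

    def coupling_pairs(self, index: FeatureIndex) -> np.ndarray:
        pairs = temporal_pairs(index)
        if self.couple_channels:
            pairs = np.vstack([pairs, spatial_pairs(index)])
        return pairs

    def build_model(self, index: FeatureIndex):
        spec = CouplingSpec(
            n_features=index.n_features,
            neighbor_pairs=self.coupling_pairs(index),
            coupling_strength=self.coupling_strength,
            regularization=self.regularization,
        )
        return build_precision(spec)


@dataclass
class CVScheme:
    """Stratified k-fold scheme; folds are deterministic given the seed."""

    k: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("fold count must be at least 2")

    def splits(self, y: np.ndarray):
        if self.stratified:
            cv = StratifiedKFold(n_splits=self.k, shuffle=True, random_state=self.seed)
        else:
            cv = KFold(n_splits=self.k, shuffle=True, random_state=self.seed)
        return list(cv.split(np.zeros(len(y)), y))


@dataclass
class EvaluationReport:
    """Per-unit accuracies with significance and importance maps.

    ``table`` has one row per analysis unit (fold, window, exemplar or
    dataset); ``predictions`` stores every per-trial prediction so reported
    accuracies can be recomputed; ``accuracy`` is the mean over units.
    """

    analysis: str
    table: pd.DataFrame
    accuracy: float
    predictions: pd.DataFrame
    importance: dict[str, ImportanceMap] = field(default_factory=dict)
    alpha: float = 0.05
    bonferroni_m: int = 1

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "analysis", self.analysis)
        out.to_csv(path, sep="\t", index=False)


def binomial_significance(
    n_correct: int,
    n_trials: int,
    majority_fraction: float,
    alpha: float = 0.05,
    m_comparisons: int = 1,
) -> tuple[float, bool]:
    """Exact one-sided binomial test against the majority-class baseline.

    Returns ``(p_value, significant)`` where the p-value is
    ``P[Binomial(n_trials, majority_fraction) >= n_correct]`` and
    significance uses the Bonferroni-corrected level ``alpha/m_comparisons``.
    """
    if not 0 <= n_correct <= n_trials:
        raise ValueError("n_correct must lie in [0, n_trials]")
    if not 0.5 <= majority_fraction <= 1.0:
        raise ValueError("majority_fraction must lie in [0.5, 1]")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be at least 1")
    p = float(stats.binom.sf(n_correct - 1, n_trials, majority_fraction))
    return p, bool(p < alpha / m_comparisons)


def _majority_fraction(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    return counts.max() / len(y)


def _subset(fm: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        X=fm.X[idx], y=fm.y[idx], feature_index=fm.feature_index, classes=fm.classes
    )


def _fit_predict(train: FeatureMatrix, test: FeatureMatrix, spec: ModelSpec):
    """Standardize on train, fit EP, predict test; returns (probs, fit)."""
    scaler = Standardizer().fit(train)
    train_z = scaler.transform(train)
    test_z = scaler.transform(test)
    prec = spec.build_model(train.feature_index)
    fit = mdl.fit(train_z, prec, spec.ep)
    probs = mdl.predict_proba(fit, test_z.X)
    return probs, fit, prec


def _row(unit, y_true, y_pred, alpha, m) -> dict:
    n = len(y_true)
    n_correct = int((y_true == y_pred).sum())
    maj = _majority_fraction(y_true)
    p, sig = binomial_significance(n_correct, n, maj, alpha, m)
    return {
        "unit": unit,
        "n": n,
        "n_correct": n_correct,
        "accuracy": n_correct / n,
        "p_value": p,
        "significant": sig,
    }


def cross_validate(
    dataset: EpochedDataset,
    model_spec: ModelSpec | None = None,
    scheme: CVScheme | None = None,
    alpha: float = 0.05,
    bonferroni_m: int = 1,
) -> EvaluationReport:
    """Stratified k-fold cross-validated decoding of the category label.

    The report carries one row per fold plus a pooled row; ``accuracy`` is
    the mean over folds, and the pooled binomial test compares the total
    correct count with the majority-class baseline over all tested trials.
    """
    model_spec = model_spec or ModelSpec()
    scheme = scheme or CVScheme()
    fm = extract_features(dataset, model_spec.interval)
    counts = np.bincount(fm.y)
    if (counts < scheme.k).any():
        raise ValueError("need at least k trials per class for k-fold CV")

    rows, preds = [], []
    imp_sum = None
    for fold, (tr, te) in enumerate(scheme.splits(fm.y)):
        if scheme.stratified and (
            len(np.unique(fm.y[tr])) < 2 or len(np.unique(fm.y[te])) < 2
        ):
            raise ValueError(f"stratification violated: class missing in fold {fold}")
        probs, fit, prec = _fit_predict(_subset(fm, tr), _subset(fm, te), model_spec)
        y_pred = (probs > 0.5).astype(int)
        rows.append(_row(f"fold{fold}", fm.y[te], y_pred, alpha, bonferroni_m))
        preds.append(
            pd.DataFrame(
                {
                    "unit": f"fold{fold}",
                    "trial": te,
                    "y_true": fm.y[te],
                    "y_pred": y_pred,
                    "p_class1": probs,
                }
            )
        )
        grid = mdl.importance_map(fit, fm.feature_index, prec.prior_variances()).values
        imp_sum = grid if imp_sum is None else imp_sum + grid

    table = pd.DataFrame(rows)
    predictions = pd.concat(preds, ignore_index=True)
    pooled = _row(
        "pooled", predictions["y_true"].values, predictions["y_pred"].values,
        alpha, bonferroni_m,
    )
    table = pd.concat([table, pd.DataFrame([pooled])], ignore_index=True)
    fold_acc = table[table["unit"] != "pooled"]["accuracy"]
    imp = ImportanceMap(
        values=imp_sum / scheme.k,
        channels=fm.feature_index.channels.copy(),
        times_ms=fm.feature_index.times_ms.copy(),
    )
    return EvaluationReport(
        analysis="cross_validation",
        table=table,
        accuracy=float(fold_acc.mean()),
        predictions=predictions,
        importance={"mean_over_folds": imp},
        alpha=alpha,
        bonferroni_m=bonferroni_m,
    )


def sliding_window(
    dataset: EpochedDataset,
    model_spec: ModelSpec | None = None,
    width: float = 40.0,
    start: float = 0.0,
    end: float = 640.0,
    scheme: CVScheme | None = None,
    alpha: float = 0.05,
    bonferroni_m: int = 1,
) -> EvaluationReport:
    """Independent cross-validated decoding in consecutive time windows.

    Defaults produce 16 windows of 40 ms covering 0-640 ms.  Folds are fixed
    per dataset and seed, so every window sees the same partition.
    """
    model_spec = model_spec or ModelSpec()
    scheme = scheme or CVScheme()
    n_win = (end - start) / width
    if abs(n_win - round(n_win)) > 1e-9 or n_win <= 0:
        raise ValueError("window width must divide the interval")
    n_win = int(round(n_win))

    rows, preds, importance = [], [], {}
    for w in range(n_win):
        w0 = start + w * width
        w1 = w0 + width
        sub_spec = replace(model_spec, interval=(w0, w1))
        rep = cross_validate(dataset, sub_spec, scheme, alpha, bonferroni_m)
        unit = f"{w0:g}-{w1:g}ms"
        pooled = rep.table[rep.table["unit"] == "pooled"].iloc[0]
        rows.append(
            {
                "unit": unit,
                "n": int(pooled["n"]),
                "n_correct": int(pooled["n_correct"]),
                "accuracy": rep.accuracy,
                "p_value": pooled["p_value"],
                "significant": pooled["significant"],
            }
        )
        p = rep.predictions.copy()
        p["unit"] = unit
        preds.append(p)
        importance[unit] = rep.importance["mean_over_folds"]

    table = pd.DataFrame(rows)
    return EvaluationReport(
        analysis="sliding_window",
        table=table,
        accuracy=float(table["accuracy"].mean()),
        predictions=pd.concat(preds, ignore_index=True),
        importance=importance,
        alpha=alpha,
        bonferroni_m=bonferroni_m,
    )


def unseen_exemplar(
    dataset: EpochedDataset,
    model_spec: ModelSpec | None = None,
    alpha: float = 0.05,
    bonferroni_m: int = 1,
    balance_training: bool = True,
    seed: int = 0,
) -> EvaluationReport:
    """Leave-one-exemplar-out category generalization.

    For every exemplar, a classifier trained on all other exemplars' trials
    predicts the category of the held-out exemplar's trials.  High accuracy
    requires category-general (not exemplar-specific) signal.

    Holding out one exemplar leaves the training set asymmetric (e.g. 3 vs
    4 exemplars): the held-out category has fewer training exemplars, which
    both unbalances the class counts and skews the margin geometry against
    the held-out category (its trials, carrying none of the learned
    exemplar signatures, land off-centre of the decision boundary).  With
    ``balance_training`` (default) one randomly chosen exemplar of the
    over-represented category is dropped from training and trial counts are
    equalized, so training is category-symmetric (deterministic given
    ``seed``).
    """
    model_spec = model_spec or ModelSpec()
    exemplars = np.unique(dataset.exemplar_ids)
    per_cat = {c: 0 for c in dataset.categories}
    for ex in exemplars:
        cat = dataset.labels[dataset.exemplar_ids == ex][0]
        per_cat[cat] += 1
    if min(per_cat.values()) < 2:
        raise ValueError("need at least two exemplars per category")

    fm = extract_features(dataset, model_spec.interval)
    rows, preds = [], []
    imp_sum = None
    rng = np.random.default_rng(seed)
    for ex in exemplars:
        te = np.flatnonzero(dataset.exemplar_ids == ex)
        tr = np.flatnonzero(dataset.exemplar_ids != ex)
        if te.size == 0:
            warnings.warn(f"exemplar {ex} has no trials; skipped", stacklevel=2)
            continue
        if balance_training:
            held_cat = dataset.labels[te[0]]
            other_exemplars = [
                e
                for e in exemplars
                if e != ex and dataset.labels[dataset.exemplar_ids == e][0] != held_cat
            ]
            if len(other_exemplars) > per_cat[held_cat] - 1:
                drop = rng.choice(other_exemplars)
                tr = tr[dataset.exemplar_ids[tr] != drop]
            y_tr = fm.y[tr]
            n_keep = min(np.bincount(y_tr, minlength=2))
            keep = []
            for cls in (0, 1):
                cls_idx = tr[y_tr == cls]
                keep.append(rng.permutation(cls_idx)[:n_keep])
            tr = np.sort(np.concatenate(keep))
        probs, fit, prec = _fit_predict(_subset(fm, tr), _subset(fm, te), model_spec)
        y_pred = (probs > 0.5).astype(int)
        rows.append(_row(str(ex), fm.y[te], y_pred, alpha, bonferroni_m))
        preds.append(
            pd.DataFrame(
                {
                    "unit": str(ex),
                    "trial": te,
                    "y_true": fm.y[te],
                    "y_pred": y_pred,
                    "p_class1": probs,
                }
            )
        )
        grid = mdl.importance_map(fit, fm.feature_index, prec.prior_variances()).values
        imp_sum = grid if imp_sum is None else imp_sum + grid

    table = pd.DataFrame(rows)
    imp = ImportanceMap(
        values=imp_sum / len(rows),
        channels=fm.feature_index.channels.copy(),
        times_ms=fm.feature_index.times_ms.copy(),
    )
    return EvaluationReport(
        analysis="unseen_exemplar",
        table=table,
        accuracy=float(table["accuracy"].mean()),
        predictions=pd.concat(preds, ignore_index=True),
        importance={"mean_over_exemplars": imp},
        alpha=alpha,
        bonferroni_m=bonferroni_m,
    )


def _stack_block_diag(blocks: list[np.ndarray]) -> np.ndarray:
    n = sum(b.shape[0] for b in blocks)
    p = sum(b.shape[1] for b in blocks)
    out = np.zeros((n, p))
    r = c = 0
    for b in blocks:
        out[r : r + b.shape[0], c : c + b.shape[1]] = b
        r += b.shape[0]
        c += b.shape[1]
    return out


def transfer_learning(
    datasets: list[EpochedDataset],
    model_spec: ModelSpec | None = None,
    scheme: CVScheme | None = None,
    alpha: float = 0.05,
    bonferroni_m: int = 1,
) -> EvaluationReport:
    """Joint decoding across datasets with a cross-dataset coupled prior.

    Each dataset keeps its own regression coefficients, but the auxiliary
    scale variables of corresponding features are coupled across datasets
    (twin pairs in the precision matrix), so the datasets share a sparsity
    profile: features useful in every dataset are favoured.  Accuracy is
    estimated with stratified k-fold CV aligned across datasets, and a joint
    importance map averages the per-dataset auxiliary variances.
    """
    model_spec = model_spec or ModelSpec()
    scheme = scheme or CVScheme()
    if len(datasets) < 2:
        raise ValueError("transfer learning needs at least two datasets")
    fms = [extract_features(d, model_spec.interval) for d in datasets]
    index = fms[0].feature_index
    for fm in fms[1:]:
        if fm.feature_index != index:
            raise ValueError("datasets must share the channel/time feature layout")
    p = index.n_features
    n_sets = len(fms)

    # coupling: temporal pairs within each dataset block + cross-dataset twins
    within = model_spec.coupling_pairs(index)
    pairs = [within + d * p for d in range(n_sets)]
    pairs.append(cross_dataset_pairs(p, n_sets))
    spec = CouplingSpec(
        n_features=n_sets * p,
        neighbor_pairs=np.vstack(pairs),
        coupling_strength=model_spec.coupling_strength,
        regularization=model_spec.regularization,
    )
    prec = build_precision(spec)

    splits = [scheme.splits(fm.y) for fm in fms]
    names = [d.modality or f"dataset{i}" for i, d in enumerate(datasets)]
    if len(set(names)) < len(names):
        names = [f"{nm}#{i}" for i, nm in enumerate(names)]
    correct = {nm: [] for nm in names}
    preds = []
    imp_sum = np.zeros(n_sets * p)
    joint_index = FeatureIndex(
        channels=np.arange(n_sets * index.n_channels), times_ms=index.times_ms
    )
    for fold in range(scheme.k):
        tr_idx = [sp[fold][0] for sp in splits]
        te_idx = [sp[fold][1] for sp in splits]
        scalers = [Standardizer().fit(_subset(fm, tr)) for fm, tr in zip(fms, tr_idx)]
        Xtr = _stack_block_diag(
            [sc.transform(_subset(fm, tr)).X for sc, fm, tr in zip(scalers, fms, tr_idx)]
        )
        ytr = np.concatenate([fm.y[tr] for fm, tr in zip(fms, tr_idx)])
        train = FeatureMatrix(
            X=Xtr, y=ytr, feature_index=joint_index, classes=fms[0].classes
        )
        fit = mdl.fit(train, prec, model_spec.ep)
        imp_sum += fit.aux_variance
        for d, nm in enumerate(names):
            Xte = np.zeros((len(te_idx[d]), n_sets * p))
            Xte[:, d * p : (d + 1) * p] = scalers[d].transform(
                _subset(fms[d], te_idx[d])
            ).X
            probs = mdl.predict_proba(fit, Xte)
            y_pred = (probs > 0.5).astype(int)
            y_true = fms[d].y[te_idx[d]]
            correct[nm].append((y_true, y_pred))
            preds.append(
                pd.DataFrame(
                    {
                        "unit": nm,
                        "trial": te_idx[d],
                        "y_true": y_true,
                        "y_pred": y_pred,
                        "p_class1": probs,
                    }
                )
            )

    rows = []
    for nm in names:
        y_true = np.concatenate([a for a, _ in correct[nm]])
        y_pred = np.concatenate([b for _, b in correct[nm]])
        rows.append(_row(nm, y_true, y_pred, alpha, bonferroni_m))
    table = pd.DataFrame(rows)

    imp_mean = imp_sum / scheme.k / prec.prior_variances()
    per_set = imp_mean.reshape(n_sets, p)
    importance = {
        nm: ImportanceMap(
            values=index.to_grid(per_set[d]),
            channels=index.channels.copy(),
            times_ms=index.times_ms.copy(),
        )
        for d, nm in enumerate(names)
    }
    importance["joint"] = ImportanceMap(
        values=index.to_grid(per_set.mean(axis=0)),
        channels=index.channels.copy(),
        times_ms=index.times_ms.copy(),
    )
    return EvaluationReport(
        analysis="transfer_learning",
        table=table,
        accuracy=float(table["accuracy"].mean()),
        predictions=pd.concat(preds, ignore_index=True),
        importance=importance,
        alpha=alpha,
        bonferroni_m=bonferroni_m,
    )
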