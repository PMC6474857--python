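"""Split-sample model evaluation and the AUC-weighted ensemble.

Predictive skill is measured by repeated stratified split-sample tests
(default 10 replicates, 75% training / 25% evaluation) scoring AUC and TSS
on the held-out rows.  The consensus model is a convex combination of the
constituent algorithms with weights proportional to their mean AUC over the
replicates; final members are refit on the full table before projection.

AUC here is the Mann–Whitney probability that a presence outscores an
absence (ties count half); TSS is the maximum over candidate thresholds of
sensitivity + specificity − 1, with prediction "suitable" iff score ≥
threshold.  Test metrics are computed unweighted — the class-balancing case
weights affect fitting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.metrics import roc_auc_score

from .errors import EnsembleError, EvaluationError, FittingError
from .niche_models import _SuitabilityModel, predict_model
from .predictors import TrainingTable
from .raster import PredictorStack, RasterGrid


def split_sample(table: TrainingTable, train_fraction: float = 0.75,
                 seed: int = 0) -> tuple[TrainingTable, TrainingTable]:
    """Stratified train/test split of a training table.

    Each class is split at ``train_fraction`` (rounded to nearest, at least
    one row on each side); the two parts are disjoint and exhaustive.
    """
    if not 0 < train_fraction < 1:
        raise EvaluationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for label in (0, 1):
        idx = np.flatnonzero(table.data["label"].to_numpy() == label)
        if idx.size < 2:
            raise EvaluationError(f"class {label} has fewer than two rows")
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    names = table.predictor_names
    return (TrainingTable(table.data.iloc[tr].reset_index(drop=True), names),
            TrainingTable(table.data.iloc[te].reset_index(drop=True), names))


def auc(scores, labels) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + ½ P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise EvaluationError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def tss(scores, labels) -> tuple[float, float]:
    """Max over thresholds of sensitivity + specificity − 1.

    Candidate thresholds are the distinct scores; a cell is predicted
    suitable iff its score ≥ threshold.  Returns (max TSS, smallest
    threshold achieving it).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise EvaluationError("TSS needs both classes present")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    thresholds = np.unique(scores)
    ge = scores[None, :] >= thresholds[:, None]
    tp = (ge & (labels == 1)).sum(axis=1)
    fp = (ge & (labels == 0)).sum(axis=1)
    stat = tp / n_pos + (1 - fp / n_neg) - 1.0
    best = float(stat.max())
    thr = float(thresholds[np.flatnonzero(np.isclose(stat, best))[0]])
    return best, thr


def evaluate_replicates(table: TrainingTable,
                        algorithms: dict[str, _SuitabilityModel],
                        n_replicates: int = 10, train_fraction: float = 0.75,
                        seed: int = 0) -> pd.DataFrame:
    """Repeated split-sample evaluation of several algorithms.

    All algorithms see the same split within a replicate.  A replicate ×
    algorithm whose fit fails is recorded as NaN and skipped with a warning
    rather than aborting the whole evaluation.  Returns one row per
    (algorithm, replicate) with columns auc, tss, tss_threshold.
    """
    records: list[dict] = []
    for rep in range(1, n_replicates + 1):
        train, test = split_sample(table, train_fraction, seed=seed * 1000 + rep)
        for name, proto in algorithms.items():
            model = clone(proto)
            try:
                model.fit(train.X, train.y, sample_weight=train.w)
                scores = model.predict(test.X)
                a = auc(scores, test.y)
                t, thr = tss(scores, test.y)
            except FittingError as exc:
                import warnings

                warnings.warn(f"replicate {rep}, {name}: {exc}")
                a = t = thr = float("nan")
            records.append({"algorithm": name, "replicate": rep,
                            "auc": a, "tss": t, "tss_threshold": thr})
    return pd.DataFrame.from_records(records)


@dataclass
class EnsembleSuitability:
    """AUC-weighted convex combination of fitted suitability models."""

    members: list
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != len(self.weights) or not len(self.members):
            raise EnsembleError("members and weights must align and be non-empty")
        if np.any(self.weights <= 0):
            raise EnsembleError("ensemble weights must be positive")
        self.weights = self.weights / self.weights.sum()

    @property
    def predictor_names_(self) -> list[str]:
        return self.members[0].predictor_names_

    def predict(self, X) -> np.ndarray:
        preds = np.column_stack([m.predict(X) for m in self.members])
        return preds @ self.weights


def build_ensemble(table: TrainingTable,
                   algorithms: dict[str, _SuitabilityModel],
                   eval_records: pd.DataFrame) -> EnsembleSuitability:
    """Refit every algorithm on the full table; weight by mean replicate AUC."""
    mean_auc = eval_records.groupby("algorithm")["auc"].mean()
    members, weights = [], []
    for name, proto in algorithms.items():
        if name not in mean_auc.index or not np.isfinite(mean_auc[name]):
            raise EnsembleError(f"no evaluation record for algorithm {name!r}")
        if mean_auc[name] <= 0:
            raise EnsembleError(f"non-positive mean AUC for {name!r}")
        model = clone(proto)
        model.fit(table.X, table.y, sample_weight=table.w)
        members.append(model)
        weights.append(float(mean_auc[name]))
    return EnsembleSuitability(members, np.asarray(weights))


def evaluate_consensus(table: TrainingTable,
                       algorithms: dict[str, _SuitabilityModel],
                       eval_records: pd.DataFrame,
                       mode: str = "holdout",
                       train_fraction: float = 0.75,
                       seed: int = 0) -> dict[str, float]:
    """AUC/TSS of the consensus (ensemble) model itself.

    ``holdout`` refits the members on a fresh stratified training split and
    scores the AUC-weighted combination on the held-out rows;
    ``resubstitution`` scores the full-data ensemble on its own training
    rows (optimistic, but sometimes the reported convention).  Weights come
    from ``eval_records`` mean AUC in both modes.
    """
    if mode == "resubstitution":
        ens = build_ensemble(table, algorithms, eval_records)
        scores = ens.predict(table.X)
        labels = table.y
    elif mode == "holdout":
        train, test = split_sample(table, train_fraction, seed)
        mean_auc = eval_records.groupby("algorithm")["auc"].mean()
        members, weights = [], []
        for name, proto in algorithms.items():
            model = clone(proto)
            model.fit(train.X, train.y, sample_weight=train.w)
            members.append(model)
            weights.append(float(mean_auc[name]))
        ens = EnsembleSuitability(members, np.asarray(weights))
        scores = ens.predict(test.X)
        labels = test.y
    else:
        raise EvaluationError(f"unknown consensus evaluation mode {mode!r}")
    a = auc(scores, labels)
    t, thr = tss(scores, labels)
    return {"auc": a, "tss": t, "tss_threshold": thr}


def predict_ensemble(ens: EnsembleSuitability, stack: PredictorStack) -> RasterGrid:
    """Cellwise weighted mean of member suitability maps over a stack."""
    maps = [predict_model(m, stack) for m in ens.members]
    vals = sum(w * m.values for w, m in zip(ens.weights, maps))
    out = maps[0].like(vals)
    out.values[out.nodata_mask] = 0.0
    return out
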