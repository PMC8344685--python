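"""Metrics, stratified 10-fold cross-validation, and the ablation harness.

Classification quality is summarised by sensitivity SE = TP/(TP+FN),
specificity SP = TN/(TN+FP), accuracy ACC = (TP+TN)/(TP+TN+FP+FN),
the Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP)),
and the threshold-independent ROC AUC. A score strictly greater than the
threshold counts as a positive call. Degenerate denominators yield NaN
(SE/SP) or 0 (MCC) with a warning.

Cross-validation uses stratified folds with a fixed seed; one model is
trained from scratch per fold and fold-mean metrics (with standard
deviations) are the primary aggregate, pooled-prediction metrics a
secondary one. The ablation harness runs the convolution filter grid
{32, 64, 32-64, 64-128} and the seven-way channel comparison
(AAC / DPC / CKSAAGP / CNN alone, and CNN fused with each descriptor) on
shared folds so rows are paired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve, auc as _auc
from sklearn.model_selection import StratifiedKFold

from .model import ModelConfig, PeptideClassifier, build_model, prepare_inputs
from .sequence_io import LabelledDataset

METRIC_NAMES = ("SE", "SP", "ACC", "MCC", "AUC")

#: Published filter-grid settings: one- and two-layer convolution stacks.
DEFAULT_FILTER_GRID = ("32", "64", "32-64", "64-128")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Confusion counts, the five summary metrics and the ROC curve."""

    counts: ConfusionCounts
    SE: float
    SP: float
    ACC: float
    MCC: float
    AUC: float
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


@dataclass
class CVResult:
    """Per-fold reports plus fold-mean/std and pooled aggregates."""

    per_fold: list[MetricsReport]
    mean: dict[str, float]
    std: dict[str, float]
    pooled: MetricsReport
    fold_assignment: np.ndarray
    seed: int
    config: ModelConfig


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricsReport:
    """Evaluate probability scores against binary labels.

    Thresholding uses the strict rule score > threshold => positive. AUC is
    computed from the score ranking and is NaN when only one class is
    present; SE/SP are NaN when their denominator is empty; an MCC with a
    zero denominator is reported as 0 with a warning.
    """
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.size != scores.size:
        raise ValueError(f"length mismatch: {labels.size} labels vs {scores.size} scores")
    if labels.size == 0:
        raise ValueError("empty input")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")

    pred = scores > threshold
    pos, neg = labels == 1, labels == 0
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & neg))
    fp = int(np.sum(pred & neg))
    fn = int(np.sum(~pred & pos))
    counts = ConfusionCounts(tp, tn, fp, fn)

    se = tp / (tp + fn) if tp + fn else _warn_nan("SE (no positives)")
    sp = tn / (tn + fp) if tn + fp else _warn_nan("SP (no negatives)")
    acc = (tp + tn) / counts.total
    denom = (tp + fn) * (tp + fp) * (tn + fn) * (tn + fp)
    if denom:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    else:
        warnings.warn("MCC denominator is zero; reporting 0 by convention", stacklevel=2)
        mcc = 0.0

    if pos.any() and neg.any():
        fpr, tpr, _ = roc_curve(labels, scores)
        auc_value = float(_auc(fpr, tpr))
        roc_points = np.column_stack([fpr, tpr])
    else:
        auc_value = float("nan")
        roc_points = np.empty((0, 2))
    return MetricsReport(counts, float(se), float(sp), float(acc), float(mcc), auc_value, roc_points)


def _warn_nan(what: str) -> float:
    warnings.warn(f"{what} is undefined for this input; reporting NaN", stacklevel=3)
    return float("nan")


def make_fold_assignment(labels: Sequence[int], n_folds: int, seed: int) -> np.ndarray:
    """Stratified record -> fold map, shared across paired experiments."""
    y = np.asarray(labels)
    counts = np.bincount(y, minlength=2)
    if n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds the smaller class size {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        assignment[test_idx] = fold
    return assignment


def cross_validate(
    dataset: LabelledDataset,
    config: ModelConfig,
    n_folds: int = 10,
    seed: int = 0,
    fold_assignment: np.ndarray | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation, training one model per fold.

    Fold seeds derive deterministically from ``seed``; passing an explicit
    ``fold_assignment`` lets several configurations share identical folds.
    """
    y = np.asarray(dataset.labels)
    if fold_assignment is None:
        fold_assignment = make_fold_assignment(y, n_folds, seed)
    else:
        fold_assignment = np.asarray(fold_assignment)
        n_folds = int(fold_assignment.max()) + 1

    X_seq, X_hf, _ = prepare_inputs(dataset, config)
    pooled_scores = np.empty(y.size, dtype=float)
    reports: list[MetricsReport] = []
    for fold in range(n_folds):
        test = fold_assignment == fold
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {fold}: training split lacks one class")
        fold_config = replace(config, seed=(seed * 1009 + fold * 97 + config.seed) % (2**31 - 1))
        model = build_model(fold_config)
        model.fit(
            X_seq[train] if X_seq is not None else None,
            X_hf[train] if X_hf is not None else None,
            y[train],
        )
        scores = model.predict_proba(
            X_seq[test] if X_seq is not None else None,
            X_hf[test] if X_hf is not None else None,
        )
        pooled_scores[test] = scores
        reports.append(compute_metrics(y[test], scores, config.threshold))

    metric_matrix = {m: np.array([r.as_dict()[m] for r in reports]) for m in METRIC_NAMES}
    mean = {m: float(np.nanmean(v)) for m, v in metric_matrix.items()}
    std = {m: float(np.nanstd(v)) for m, v in metric_matrix.items()}
    pooled = compute_metrics(y, pooled_scores, config.threshold)
    return CVResult(reports, mean, std, pooled, fold_assignment, seed, config)


def run_filter_grid(
    dataset: LabelledDataset,
    grid: Sequence[str] = DEFAULT_FILTER_GRID,
    base_config: ModelConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> dict[str, CVResult]:
    """Cross-validate each convolution filter setting on shared folds.

    Settings are strings like ``"32"`` or ``"32-64"`` (two stacked
    convolutions before pooling).
    """
    if not grid:
        raise ValueError("empty filter grid")
    base_config = base_config or ModelConfig()
    assignment = make_fold_assignment(dataset.labels, n_folds, seed)
    results: dict[str, CVResult] = {}
    for setting in grid:
        filters = tuple(int(part) for part in str(setting).split("-"))
        config = replace(base_config, conv_filters=filters)
        results[str(setting)] = cross_validate(
            dataset, config, seed=seed, fold_assignment=assignment
        )
    return results


def run_channel_comparison(
    dataset: LabelledDataset,
    base_config: ModelConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> dict[str, CVResult]:
    """Cross-validate the seven channel/fusion configurations on shared folds.

    Rows: each descriptor alone (handcrafted channel only), the CNN channel
    alone, and the CNN fused with each descriptor.
    """
    base_config = base_config or ModelConfig()
    assignment = make_fold_assignment(dataset.labels, n_folds, seed)
    rows = {
        "AAC": replace(base_config, channels="hf_only", hf_scheme="AAC"),
        "DPC": replace(base_config, channels="hf_only", hf_scheme="DPC"),
        "CKSAAGP": replace(base_config, channels="hf_only", hf_scheme="CKSAAGP"),
        "CNN": replace(base_config, channels="cnn_only", hf_scheme="none"),
        "CNN+AAC": replace(base_config, channels="dual", hf_scheme="AAC"),
        "CNN+DPC": replace(base_config, channels="dual", hf_scheme="DPC"),
        "CNN+CKSAAGP": replace(base_config, channels="dual", hf_scheme="CKSAAGP"),
    }
    return {
        name: cross_validate(dataset, config, seed=seed, fold_assignment=assignment)
        for name, config in rows.items()
    }


def evaluate_on_test(model: PeptideClassifier, test: LabelledDataset) -> MetricsReport:
    """Evaluate a trained model on an independent labelled test set."""
    X_seq, X_hf, y = prepare_inputs(test, model.config, model.alphabet)
    scores = model.predict_proba(X_seq, X_hf)
    return compute_metrics(y, scores, model.config.threshold)


def results_table(results: Mapping[str, CVResult], decimals: int | None = 2) -> pd.DataFrame:
    """Fold-mean metrics, one row per configuration; best AUC row flagged.

    ``decimals=None`` keeps full precision for machine-readable output.
    """
    frame = pd.DataFrame({name: r.mean for name, r in results.items()}).T[list(METRIC_NAMES)]
    best = frame["AUC"].idxmax()
    if decimals is not None:
        frame = frame.round(decimals)
    frame["best"] = [name == best for name in frame.index]
    return frame


def cv_to_dict(result: CVResult) -> dict:
    """Machine-readable CV summary (full precision, config echo, seed)."""
    return {
        "seed": result.seed,
        "config": result.config.to_dict(),
        "mean": result.mean,
        "std": result.std,
        "pooled": result.pooled.as_dict(),
        "per_fold": [r.as_dict() for r in result.per_fold],
    }


def write_roc(report: MetricsReport, path: str | Path) -> None:
    """Write ROC points as a two-column (FPR, TPR) TSV."""
    pd.DataFrame(report.roc_points, columns=["FPR", "TPR"]).to_csv(path, sep="\t", index=False)
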