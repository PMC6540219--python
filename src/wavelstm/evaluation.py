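"""Diagnostic metrics, split protocols, and the experiment runner.

Binary metrics follow the standard diagnostic definitions with the malignant
class as positive:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    Youden's J  = sensitivity + specificity - 1

Multiclass metrics use unweighted one-vs-rest macro averaging by default (a
micro-averaged option is provided; on balanced test sets micro sensitivity
collapses to accuracy).  The evaluation protocol is either repeated stratified
70/30 holdout (five repeats by default, equal per-class counts in train and
test) or stratified k-fold cross-validation; results tables carry one row per
split plus a mean +/- sample-standard-deviation summary.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .baselines import BaselineConfig, fit_baseline, predict_baseline
from .network import NetworkTopology, TrainingConfig, predict, train
from .transforms import reduce_features

__all__ = [
    "confusion_matrix",
    "MetricsReport",
    "binary_metrics",
    "macro_metrics",
    "SplitPlan",
    "make_split_plan",
    "PipelineSpec",
    "ResultsTable",
    "run_experiment",
    "roc_points",
]


def confusion_matrix(
    true_labels: np.ndarray, predicted_labels: np.ndarray, n_classes: int
) -> np.ndarray:
    """Counts grid with rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if t.size and (t.min() < 0 or p.min() < 0 or max(t.max(), p.max()) >= n_classes):
        raise ValueError("labels out of range")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy/sensitivity/specificity as percentages, Youden's J unitless.

    Metrics whose denominator was zero are NaN and listed in ``undefined``
    rather than silently reported as zero.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    youden: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "youden": self.youden}

    def rounded(self) -> dict[str, float]:
        """Display rounding: one decimal for percentages, two for J."""
        return {"accuracy": round(self.accuracy, 1),
                "sensitivity": round(self.sensitivity, 1),
                "specificity": round(self.specificity, 1),
                "youden": round(self.youden, 2)}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def binary_metrics(cm: np.ndarray, positive: int = 1) -> MetricsReport:
    """Diagnostic metrics of a 2-class confusion matrix.

    ``positive`` selects the positive (malignant) class index; the default 1
    matches the generator convention of class 1 being the sparser-spiking,
    malignant-like class.
    """
    cm = np.asarray(cm)
    if cm.shape != (2, 2):
        raise ValueError("binary_metrics requires a 2 x 2 confusion matrix")
    neg = 1 - positive
    TP = float(cm[positive, positive])
    TN = float(cm[neg, neg])
    FP = float(cm[neg, positive])
    FN = float(cm[positive, neg])
    acc = _ratio(TP + TN, TP + TN + FP + FN)
    sens = _ratio(TP, TP + FN)
    spec = _ratio(TN, TN + FP)
    youden = sens + spec - 1.0
    undefined = tuple(
        name for name, val in
        (("accuracy", acc), ("sensitivity", sens), ("specificity", spec))
        if math.isnan(val)
    )
    if undefined:
        youden = math.nan
        undefined = undefined + ("youden",)
    return MetricsReport(accuracy=100 * acc, sensitivity=100 * sens,
                         specificity=100 * spec, youden=youden,
                         undefined=undefined)


def macro_metrics(
    cm: np.ndarray, average: Literal["macro", "micro"] = "macro"
) -> MetricsReport:
    """One-vs-rest multiclass metrics.

    ``macro`` (default) averages per-class sensitivity/specificity with equal
    weight; ``micro`` pools the one-vs-rest counts first (on balanced test
    sets micro sensitivity equals accuracy).  J is computed from the averaged
    sensitivity/specificity.
    """
    cm = np.asarray(cm, dtype=np.float64)
    k = cm.shape[0]
    if cm.ndim != 2 or cm.shape[1] != k or k < 2:
        raise ValueError("confusion matrix must be square with >= 2 classes")
    total = cm.sum()
    acc = _ratio(cm.trace(), total)
    tp = np.diag(cm)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    undefined: tuple[str, ...] = ()
    if average == "micro":
        sens = _ratio(tp.sum(), tp.sum() + fn.sum())
        spec = _ratio(tn.sum(), tn.sum() + fp.sum())
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            sens_c = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
            spec_c = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        if np.isnan(sens_c).any() or np.isnan(spec_c).any():
            undefined = ("sensitivity", "specificity", "youden")
        sens = float(np.mean(sens_c))
        spec = float(np.mean(spec_c))
    youden = sens + spec - 1.0
    if math.isnan(acc):
        undefined = undefined + ("accuracy",)
    return MetricsReport(accuracy=100 * acc, sensitivity=100 * sens,
                         specificity=100 * spec, youden=youden,
                         undefined=undefined)


# ---------------------------------------------------------------------------
# Split protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """A list of (train, test) index pairs under a named protocol."""

    splits: tuple[tuple[np.ndarray, np.ndarray], ...]
    protocol: Literal["repeated_holdout", "kfold"]
    parameter: float  # train fraction or k
    seed: int

    @property
    def n_splits(self) -> int:
        return len(self.splits)


def make_split_plan(
    labels: np.ndarray,
    protocol: Literal["repeated_holdout", "kfold"] = "repeated_holdout",
    fraction_or_k: float = 0.7,
    repeats: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Build a stratified split plan.

    ``repeated_holdout`` draws ``repeats`` independent random splits with
    ``floor(fraction * n_c)`` training samples per class (remainder to test),
    e.g. 56/56 at 70% gives 39+39 train and 17+17 test.  ``kfold`` partitions
    each class round-robin into ``k`` disjoint test folds covering every
    sample exactly once.  Deterministic given ``seed``.
    """
    y = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(seed)
    class_indices = [np.flatnonzero(y == c) for c in np.unique(y)]
    if any(idx.size < 2 for idx in class_indices):
        raise ValueError("every class needs at least two members")
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    if protocol == "repeated_holdout":
        frac = float(fraction_or_k)
        if not 0.0 < frac < 1.0:
            raise ValueError("train fraction must be in (0, 1)")
        for _ in range(repeats):
            tr_parts, te_parts = [], []
            for idx in class_indices:
                n_train = int(frac * idx.size)  # floor; remainder tests
                if n_train == 0 or n_train == idx.size:
                    raise ValueError("split leaves a class empty on one side")
                perm = rng.permutation(idx)
                tr_parts.append(perm[:n_train])
                te_parts.append(perm[n_train:])
            splits.append((np.sort(np.concatenate(tr_parts)),
                           np.sort(np.concatenate(te_parts))))
    elif protocol == "kfold":
        k = int(fraction_or_k)
        if k < 2 or any(idx.size < k for idx in class_indices):
            raise ValueError("k must be >= 2 and no larger than any class size")
        fold_members: list[list[np.ndarray]] = [[] for _ in range(k)]
        for idx in class_indices:
            perm = rng.permutation(idx)
            for j in range(k):
                fold_members[j].append(perm[j::k])
        all_idx = np.arange(y.size)
        for j in range(k):
            test = np.sort(np.concatenate(fold_members[j]))
            train = np.setdiff1d(all_idx, test)
            splits.append((train, test))
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return SplitPlan(splits=tuple(splits), protocol=protocol,
                     parameter=float(fraction_or_k), seed=seed)


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineSpec:
    """One experimental arm: a transform choice plus a classifier choice."""

    transform: Literal["dwt", "dct", "fwht", "none"] = "dwt"
    classifier: Literal["lstm", "knn", "svm"] = "lstm"
    wavelet_order: int = 7
    coefficients: Literal["approximation", "detail"] = "approximation"
    training: TrainingConfig = TrainingConfig()
    topology: NetworkTopology = NetworkTopology()
    baseline: BaselineConfig = BaselineConfig()
    positive_class: int = 1
    multiclass_average: Literal["macro", "micro"] = "macro"


@dataclass
class ResultsTable:
    """Per-split metric rows plus their mean +/- std (ddof = 1) summary."""

    pipeline: PipelineSpec
    per_split: pd.DataFrame
    confusions: list[np.ndarray]

    _METRICS = ("accuracy", "sensitivity", "specificity", "youden")

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(self.per_split[m].mean()) for m in self._METRICS}

    @property
    def std(self) -> dict[str, float]:
        return {m: float(self.per_split[m].std(ddof=1)) for m in self._METRICS}

    def summary(self) -> pd.DataFrame:
        df = self.per_split.copy()
        df.loc["mean"] = [float(self.per_split[c].mean()) for c in df.columns]
        df.loc["std"] = [float(self.per_split[c].std(ddof=1)) for c in df.columns]
        return df

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pipeline": _jsonable(dataclasses.asdict(self.pipeline)),
            "per_split": self.per_split.to_dict(orient="records"),
            "mean": self.mean,
            "std": self.std,
            "confusion_matrices": [cm.tolist() for cm in self.confusions],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_csv(self, path: str | Path) -> None:
        self.summary().to_csv(path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def run_experiment(
    features: np.ndarray,
    labels: np.ndarray,
    pipeline: PipelineSpec,
    plan: SplitPlan,
) -> ResultsTable:
    """Run one pipeline arm over every split of a plan and aggregate.

    The transforms are data-independent linear maps, so the whole matrix is
    transformed once up front — there is no statistic to fit on training rows.
    A classifier is trained per split on the training rows and evaluated on
    the held-out rows; a failure in any split aborts the run rather than
    aggregating partial results.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    n_classes = int(y.max()) + 1
    Xt = reduce_features(
        X, pipeline.transform,
        wavelet_order=pipeline.wavelet_order,
        coefficients=pipeline.coefficients,
    )
    rows = []
    confusions: list[np.ndarray] = []
    for split_no, (tr, te) in enumerate(plan.splits):
        if pipeline.classifier == "lstm":
            model, _ = train(
                Xt[tr], y[tr],
                config=dataclasses.replace(
                    pipeline.training, seed=pipeline.training.seed + split_no
                ),
                topology=pipeline.topology,
            )
            pred, _ = predict(model, Xt[te])
        else:
            cfg = dataclasses.replace(
                pipeline.baseline,
                method=pipeline.classifier,
                seed=pipeline.baseline.seed + split_no,
            )
            fitted = fit_baseline(Xt[tr], y[tr], cfg)
            pred = predict_baseline(fitted, Xt[te])
        cm = confusion_matrix(y[te], pred, n_classes)
        confusions.append(cm)
        report = (
            binary_metrics(cm, positive=pipeline.positive_class)
            if n_classes == 2
            else macro_metrics(cm, average=pipeline.multiclass_average)
        )
        rows.append({"split": split_no, **report.as_dict()})
    table = pd.DataFrame(rows).set_index("split")
    return ResultsTable(pipeline=pipeline, per_split=table, confusions=confusions)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_points(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep over the unique scores, plus its area.

    ``scores`` are positive-class probabilities (or any monotone score);
    ``labels`` are binary with 1 = positive.  The curve runs from (0, 0) to
    (1, 1); the area is the trapezoidal integral, which equals the
    Mann-Whitney concordance probability with ties counted half.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D of equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # collapse runs of tied scores to one operating point
    distinct = np.flatnonzero(np.diff(s_sorted) != 0)
    cut = np.concatenate([distinct, [s.size - 1]])
    tpr = np.concatenate([[0.0], tps[cut] / n_pos])
    fpr = np.concatenate([[0.0], fps[cut] / n_neg])
    area = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, area
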