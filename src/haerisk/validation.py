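"""Model validation: stratified split, confusion-matrix panel, ROC/AUC.

The validation stage mirrors the published protocol: a 70/30 train/test
split (stratified by outcome by default — with ~440 records and ~39%
positives an unstratified split can produce unstable panels), posterior
probabilities thresholded at 0.5 into high/low predictions, and an
eight-metric confusion-matrix panel per partition:

    accuracy, balanced accuracy, sensitivity, specificity, PPV, NPV,
    detection rate (TP/N), detection prevalence ((TP+FP)/N)

plus AUC in two modes.  *Probability mode* is the standard ROC over the
posterior scores (the defensible statistic, equal to the Mann-Whitney
pairwise-comparison probability).  *Label mode* is the two-point ROC of the
thresholded classifier — a straight-line curve whose area is exactly
(sensitivity + specificity)/2 — kept because a classifier reported only in
discrete form yields exactly such curves.

Degenerate denominators yield NaN ("undefined"), never a coerced 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .bn_fit import FitConfig, FittedBN, fit_network
from .bn_infer import score_cohort
from .cohort_synth import Cohort
from .model_spec import DagModel, ModelError


class SplitError(ModelError):
    """The requested train/test split cannot be formed."""


class AucUndefinedError(ModelError):
    """ROC/AUC requires both classes to be present."""


@dataclass(frozen=True)
class SplitSpec:
    """Train fraction, RNG seed, and outcome stratification flag."""

    train_fraction: float = 0.70
    seed: int = 0
    stratify: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise SplitError(
                f"train fraction must be in (0, 1), got {self.train_fraction}"
            )


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with positive class = outcome high."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int((y_true & y_pred).sum()),
            fp=int((~y_true & y_pred).sum()),
            tn=int((~y_true & ~y_pred).sum()),
            fn=int((y_true & ~y_pred).sum()),
        )


@dataclass
class MetricsReport:
    """The eight-metric panel; NaN marks an undefined (0/0) metric."""

    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    detection_rate: float
    detection_prevalence: float
    auc_probability: float = float("nan")
    auc_label: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "detection_rate": self.detection_rate,
            "detection_prevalence": self.detection_prevalence,
            "auc_probability": self.auc_probability,
            "auc_label": self.auc_label,
        }


@dataclass
class RocCurve:
    """Ordered (FPR, TPR) points from (0,0) to (1,1); AUC by trapezoid rule."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    mode: str


# -- operations ------------------------------------------------------------


def split_cohort(cohort: Cohort, spec: SplitSpec = SplitSpec()) -> tuple[Cohort, Cohort]:
    """Disjoint, exhaustive train/test partition, deterministic given seed.

    Within each stratum the train share is ``floor(fraction * stratum)``;
    the remainder goes to test.  Unstratified splits treat the whole cohort
    as one stratum.
    """
    n = len(cohort)
    if n < 10:
        raise SplitError(f"cohort too small to split ({n} records)")
    outcome = cohort.schema.outcome.name
    rng = np.random.default_rng(spec.seed)
    if spec.stratify:
        groups = [
            np.flatnonzero((cohort.frame[outcome] == cat).to_numpy())
            for cat in cohort.schema.outcome.categories
        ]
        for cat, idx in zip(cohort.schema.outcome.categories, groups):
            if idx.size == 0:
                raise SplitError(f"outcome stratum {cat!r} is empty")
    else:
        groups = [np.arange(n)]
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for idx in groups:
        perm = rng.permutation(idx)
        k = int(np.floor(spec.train_fraction * idx.size))
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    prov = dict(cohort.provenance)
    split_meta = {
        "train_fraction": spec.train_fraction,
        "seed": spec.seed,
        "stratify": spec.stratify,
    }
    train = Cohort(
        cohort.frame.iloc[tr].reset_index(drop=True),
        cohort.schema,
        {**prov, "split": {**split_meta, "partition": "train"}},
    )
    test = Cohort(
        cohort.frame.iloc[te].reset_index(drop=True),
        cohort.schema,
        {**prov, "split": {**split_meta, "partition": "test"}},
    )
    return train, test


def classify(p: float, threshold: float = 0.5) -> bool:
    """True (predict high risk) iff ``p >= threshold``.

    The tie at exactly the threshold goes to *high* — conservative toward
    detecting at-risk patients.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must be in [0, 1], got {p}")
    return p >= threshold


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The eight-metric panel from a confusion matrix.

    Balanced accuracy is computed as (sensitivity + specificity)/2 and
    detection rate as TP/N, so the panel identities hold exactly.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.n,
        balanced_accuracy=(sens + spec) / 2.0,
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        detection_rate=cm.tp / cm.n,
        detection_prevalence=(cm.tp + cm.fp) / cm.n,
    )


def roc_auc(
    scores: Sequence[float],
    y_true: Sequence[bool],
    mode: str = "probability",
    threshold: float = 0.5,
) -> RocCurve:
    """ROC curve and trapezoid AUC.

    ``probability`` mode sweeps all score thresholds (equal scores grouped);
    ``label`` mode is the two-point curve of the classifier thresholded at
    ``threshold``, whose AUC is exactly (sensitivity + specificity)/2.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true, dtype=bool)
    if y.all() or not y.any():
        raise AucUndefinedError("ROC/AUC undefined: only one class present")
    if mode == "probability":
        fpr, tpr, _ = _sk_roc_curve(y.astype(int), scores, drop_intermediate=False)
        if fpr[0] != 0.0 or tpr[0] != 0.0:
            fpr = np.concatenate([[0.0], fpr])
            tpr = np.concatenate([[0.0], tpr])
        if fpr[-1] != 1.0 or tpr[-1] != 1.0:
            fpr = np.concatenate([fpr, [1.0]])
            tpr = np.concatenate([tpr, [1.0]])
        auc = float(np.trapezoid(tpr, fpr))
        return RocCurve(fpr, tpr, auc, "probability")
    if mode == "label":
        pred = scores >= threshold
        cm = ConfusionMatrix.from_predictions(y, pred)
        sens = cm.tp / (cm.tp + cm.fn)
        spec = cm.tn / (cm.tn + cm.fp)
        fpr = np.array([0.0, 1.0 - spec, 1.0])
        tpr = np.array([0.0, sens, 1.0])
        auc = float(np.trapezoid(tpr, fpr))
        return RocCurve(fpr, tpr, auc, "label")
    raise ValueError(f"mode must be 'probability' or 'label', got {mode!r}")


@dataclass
class PartitionResult:
    metrics: MetricsReport
    roc_probability: RocCurve
    roc_label: RocCurve
    confusion: ConfusionMatrix


@dataclass
class ValidationResult:
    train: PartitionResult
    test: PartitionResult
    model: FittedBN
    split: SplitSpec

    def as_dict(self) -> dict:
        return {
            "train": self.train.metrics.as_dict(),
            "test": self.test.metrics.as_dict(),
        }


def _evaluate_partition(
    bn: FittedBN, cohort: Cohort, threshold: float
) -> PartitionResult:
    outcome = cohort.schema.outcome
    scores = score_cohort(bn, cohort.frame)
    high = outcome.categories[outcome.index_of("high")]
    y = (cohort.frame[outcome.name] == high).to_numpy()
    pred = scores >= threshold
    cm = ConfusionMatrix.from_predictions(y, pred)
    metrics = compute_metrics(cm)
    roc_p = roc_auc(scores, y, mode="probability")
    roc_l = roc_auc(scores, y, mode="label", threshold=threshold)
    metrics.auc_probability = roc_p.auc
    metrics.auc_label = roc_l.auc
    return PartitionResult(metrics, roc_p, roc_l, cm)


def validate_pipeline(
    cohort: Cohort,
    dag: DagModel | None = None,
    fit_config: FitConfig = FitConfig(),
    split_spec: SplitSpec = SplitSpec(),
    threshold: float = 0.5,
) -> ValidationResult:
    """Fit on the train partition, score both partitions, emit both panels."""
    dag = dag or cohort.schema
    train, test = split_cohort(cohort, split_spec)
    bn = fit_network(train, dag, fit_config)
    return ValidationResult(
        train=_evaluate_partition(bn, train, threshold),
        test=_evaluate_partition(bn, test, threshold),
        model=bn,
        split=split_spec,
    )
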