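"""Order/disorder boundary in charge-hydropathy space: linear-SVM fitting,
confusion-matrix metrics and ROC/AUC benchmarking.

The boundary is kept in the canonical form

    score = a * <H_pH> - |NCPR| - b

with positive scores on the folded side. The default coefficients
(a, b) = (2.775, 1.118) come from a linear-kernel SVM fit to bibliographic
order/disorder datapoints; the classic Uversky boundary
(a, b) = (2.785, 1.151) is available as a preset. In all binary metrics the
positive class is *disordered* (an unfolded sequence correctly predicted
unfolded is a true positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn import metrics as _skmetrics
from sklearn.svm import SVC

LABEL_ORDERED = "ordered"
LABEL_DISORDERED = "disordered"

#: fixed soft-margin regularization constant for the linear SVM fit
SVM_C = 10.0


class BoundaryFitError(ValueError):
    """The SVM fit is impossible or does not satisfy the C-H orientation."""


@dataclass(frozen=True)
class BoundaryModel:
    """Linear order/disorder boundary ``score = a*H - |NCPR| - b``."""

    a: float
    b: float
    margin: float = 0.02

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary coefficient a must be positive")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")

    def score(self, mean_h: float, ncpr_abs: float):
        return self.a * np.asarray(mean_h) - np.asarray(ncpr_abs) - self.b


#: SVM-derived pH-dependent boundary, with its +-0.02 confidence margin
DEFAULT_BOUNDARY = BoundaryModel(a=2.775, b=1.118, margin=0.02)
#: Uversky's neutral-pH charge-hydropathy boundary
UVERSKY_BOUNDARY = BoundaryModel(a=2.785, b=1.151, margin=0.0)


@dataclass
class LabeledPoint:
    """One labeled charge-hydropathy datapoint at a given pH."""

    id: str
    mean_h: float
    ncpr_abs: float
    ph: float
    label: str  # "ordered" | "disordered"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (LABEL_ORDERED, LABEL_DISORDERED):
            raise ValueError(f"label must be ordered|disordered, got {self.label!r}")
        if not (0.0 <= self.mean_h <= 1.0):
            raise ValueError(f"mean_h must lie in [0, 1], got {self.mean_h}")
        if self.ncpr_abs < 0:
            raise ValueError(f"ncpr_abs must be >= 0, got {self.ncpr_abs}")


def fit_boundary(points: Sequence[LabeledPoint], C: float = SVM_C) -> BoundaryModel:
    """Fit the maximum-margin linear boundary to labeled C-H datapoints.

    A soft-margin linear-kernel SVM is trained on (mean_h, ncpr_abs) with a
    fixed regularization constant, then rescaled to the canonical form by
    dividing the separating hyperplane by (minus) its |NCPR| coefficient.
    The reported margin is the SVM margin half-width in score units.

    Deterministic given the data (the linear-kernel SMO solve has no random
    component at this problem size).
    """
    labels = {p.label for p in points}
    if len(labels) < 2:
        raise BoundaryFitError("both ordered and disordered points are required")
    for lab in (LABEL_ORDERED, LABEL_DISORDERED):
        if sum(p.label == lab for p in points) < 2:
            raise BoundaryFitError(f"need at least 2 {lab} points")
    X = np.array([[p.mean_h, p.ncpr_abs] for p in points])
    if np.allclose(X, X[0]):
        raise BoundaryFitError("degenerate input: all points identical")
    y = np.array([1 if p.label == LABEL_ORDERED else 0 for p in points])
    svc = SVC(kernel="linear", C=C)
    svc.fit(X, y)
    w_h, w_n = svc.coef_[0]
    b0 = svc.intercept_[0]
    # decision_function > 0 <=> ordered; canonical form needs the |NCPR|
    # coefficient to be exactly -1 with hydrophobicity on the folded side.
    if w_h <= 0 or w_n > abs(w_h) * 1e-9:
        raise BoundaryFitError(
            "fitted separator does not satisfy the charge-hydropathy "
            f"orientation (coefficients H={w_h:.4g}, |NCPR|={w_n:.4g})"
        )
    if abs(w_n) <= abs(w_h) * 1e-9:
        # |NCPR| carried no information (e.g. all points at zero charge):
        # the boundary is vertical in H; report it with unit H coefficient.
        return BoundaryModel(a=1.0, b=-b0 / w_h, margin=1.0 / w_h)
    a = -w_h / w_n
    b = b0 / w_n
    margin = 1.0 / abs(w_n)
    return BoundaryModel(a=a, b=b, margin=margin)


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion matrix with *disordered* as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The seven binary-classification metrics; undefined ratios are NaN
    and their names are listed in ``undefined``."""

    sensitivity: float
    specificity: float
    precision: float
    fdr: float
    accuracy: float
    f1: float
    mcc: float
    undefined: frozenset = frozenset()


def _ratio(num: float, den: float, name: str, undefined: set) -> float:
    if den == 0:
        undefined.add(name)
        return math.nan
    return num / den


def metrics_from_counts(counts: ConfusionCounts) -> MetricsReport:
    """Compute sensitivity, specificity, precision, FDR, accuracy, F1, MCC.

    Sensitivity = TP/(TP+FN); Specificity = TN/(TN+FP);
    Precision = TP/(TP+FP); FDR = FP/(FP+TP) = 1 - precision;
    Accuracy = (TP+TN)/total; F1 = 2*precision*sensitivity/(precision+sensitivity);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: set[str] = set()
    sens = _ratio(tp, tp + fn, "sensitivity", undefined)
    spec = _ratio(tn, tn + fp, "specificity", undefined)
    prec = _ratio(tp, tp + fp, "precision", undefined)
    fdr = _ratio(fp, fp + tp, "fdr", undefined)
    acc = _ratio(tp + tn, counts.total, "accuracy", undefined)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", undefined)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", undefined)
    return MetricsReport(sens, spec, prec, fdr, acc, f1, mcc, frozenset(undefined))


def evaluate(
    points: Sequence[LabeledPoint], boundary: BoundaryModel = DEFAULT_BOUNDARY
) -> tuple[ConfusionCounts, MetricsReport]:
    """Classify points with the boundary and compute the metrics report.

    A point is predicted disordered when its score is negative; points
    inside the confidence margin are resolved by sign.
    """
    if not points:
        raise ValueError("no points to evaluate")
    tp = tn = fp = fn = 0
    for p in points:
        pred_disordered = boundary.score(p.mean_h, p.ncpr_abs) < 0
        if p.label == LABEL_DISORDERED:
            if pred_disordered:
                tp += 1
            else:
                fn += 1
        else:
            if pred_disordered:
                fp += 1
            else:
                tn += 1
    counts = ConfusionCounts(tp, tn, fp, fn)
    return counts, metrics_from_counts(counts)


@dataclass
class RocResult:
    """ROC curve (threshold sweep) and its area under the curve."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(
    scores: Iterable[float], labels: Iterable[str] | Iterable[int]
) -> RocResult:
    """ROC analysis of a disorder score (higher = more disordered).

    ``labels`` may be "ordered"/"disordered" strings or 0/1 integers with
    1 = disordered (positive class). The AUC equals the Mann-Whitney
    probability that a random disordered item outscores a random ordered
    one, with half credit for ties.
    """
    scores = np.asarray(list(scores), dtype=float)
    y = np.array(
        [
            1 if lab in (LABEL_DISORDERED, 1, True) else 0
            for lab in labels
        ]
    )
    if len(set(y)) < 2:
        raise ValueError("both ordered and disordered labels are required")
    fpr, tpr, thresholds = _skmetrics.roc_curve(y, scores, drop_intermediate=False)
    auc = float(_skmetrics.roc_auc_score(y, scores))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)
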