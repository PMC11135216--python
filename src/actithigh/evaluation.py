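"""Confusion matrices, F-measure, cross-validation, merging, duration error.

Conventions shared by every report in the package:

* Confusion matrices have ground truth on rows, predictions on columns, in
  the canonical class order, so tables from different runs are comparable.
* The per-class metrics are sensitivity (recall, TP / row sum), positive
  predictive value (precision, TP / column sum) and their harmonic mean, the
  F-measure. Any 0/0 is defined as 0 (with a warning), never NaN, so absent
  classes do not poison macro averages.
* The macro average is the unweighted mean of the per-class F-measures.
* The duration error for a class over a session is
  ``|duration_alg - duration_gt| / duration_gt`` where ``duration_alg``
  counts *all* samples predicted as the class (errors above 100% are
  therefore possible when a class is heavily over-predicted) and each sample
  stands for ``dt`` seconds (0.5 s for half-overlapping 1 s windows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from . import classifier as clf
from .taxonomy import OTHER_CLASS, MergeScheme

#: Seconds represented by one window-level sample in second-by-second streams
#: built from 1 s windows stepping by 0.5 s.
DEFAULT_DT_S = 0.5


@dataclass
class ConfusionMatrix:
    """Ground-truth rows x predicted columns over an ordered class list."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}; got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, c: str) -> int:
        try:
            return self.classes.index(c)
        except ValueError:
            raise KeyError(f"class {c!r} not in confusion matrix") from None


@dataclass
class ClassMetrics:
    sensitivity: float
    ppv: float
    f_measure: float


@dataclass
class DurationError:
    duration_alg: float
    duration_gt: float
    error: float


def confusion(truth, pred, classes: tuple[str, ...]) -> ConfusionMatrix:
    """Count (truth, prediction) pairs into a matrix over ``classes``."""
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if len(truth) != len(pred):
        raise ValueError("truth and prediction vectors differ in length")
    unknown = (set(truth) | set(pred)) - set(classes)
    if unknown:
        raise ValueError(f"labels not in class list: {sorted(map(str, unknown))}")
    if len(truth) == 0:
        return ConfusionMatrix(tuple(classes), np.zeros((len(classes),) * 2, dtype=np.int64))
    counts = _sk_confusion(truth, pred, labels=list(classes))
    return ConfusionMatrix(tuple(classes), counts)


def class_metrics(cm: ConfusionMatrix, c: str) -> ClassMetrics:
    """Sensitivity, PPV and F-measure for one class of a confusion matrix."""
    i = cm.index(c)
    tp = float(cm.counts[i, i])
    row = float(cm.counts[i, :].sum())
    col = float(cm.counts[:, i].sum())
    if row == 0 or col == 0:
        warnings.warn(
            f"class {c!r} has no {'ground-truth' if row == 0 else 'predicted'} "
            "samples; reporting 0 metrics",
            stacklevel=2,
        )
    sens = tp / row if row > 0 else 0.0
    ppv = tp / col if col > 0 else 0.0
    f = 2 * sens * ppv / (sens + ppv) if sens + ppv > 0 else 0.0
    return ClassMetrics(sensitivity=sens, ppv=ppv, f_measure=f)


def macro_f(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F-measures over the classes of ``cm``.

    The 'other' pseudo-class (predictions of merged-away classes) already
    counts as an error against each sample's true class, so it is not
    averaged as a class of its own.
    """
    classes = [c for c in cm.classes if c != OTHER_CLASS]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.mean([class_metrics(cm, c).f_measure for c in classes]))


def merge(truth, pred, scheme: MergeScheme) -> tuple[np.ndarray, np.ndarray]:
    """Apply a merge scheme to paired label streams.

    Samples whose ground truth is excluded are dropped. Remaining labels are
    mapped to coarse classes on both sides; a retained sample *predicted* as
    an excluded (unmapped) class becomes :data:`~actithigh.taxonomy.OTHER_CLASS`,
    which counts as an error against its true class.
    """
    t_out, p_out = [], []
    for t, p in zip(truth, pred):
        if t in scheme.excluded:
            continue
        ct = scheme.apply(t)
        if ct is None:
            raise ValueError(f"ground-truth label {t!r} neither mapped nor excluded")
        cp = scheme.apply(p)
        p_out.append(OTHER_CLASS if cp is None else cp)
        t_out.append(ct)
    return np.array(t_out, dtype=object), np.array(p_out, dtype=object)


def merged_confusion(truth, pred, scheme: MergeScheme) -> ConfusionMatrix:
    """Confusion matrix after merging.

    The matrix is restricted to coarse classes that actually occur in the
    merged streams, so short sessions are not scored against behaviors they
    never contained; an 'other' pseudo-class column is added only when used.
    """
    t2, p2 = merge(truth, pred, scheme)
    present = set(t2) | set(p2)
    classes = tuple(c for c in scheme.coarse_classes() if c in present)
    if OTHER_CLASS in present:
        classes = classes + (OTHER_CLASS,)
    return confusion(t2, p2, classes)


def duration_error(truth, pred, c: str, dt_s: float = DEFAULT_DT_S) -> DurationError:
    """Relative duration error for class ``c`` over a session."""
    truth = np.asarray(truth, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if len(truth) != len(pred):
        raise ValueError("truth and prediction vectors differ in length")
    d_gt = dt_s * float(np.sum(truth == c))
    if d_gt == 0:
        raise ValueError(f"class {c!r} absent from ground truth; duration error undefined")
    d_alg = dt_s * float(np.sum(pred == c))
    return DurationError(duration_alg=d_alg, duration_gt=d_gt, error=abs(d_alg - d_gt) / d_gt)


def stratified_kfold(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    classes: tuple[str, ...] | None = None,
    n_trees: int = clf.DEFAULT_N_TREES,
) -> ConfusionMatrix:
    """Stratified k-fold cross-validation, pooled into one confusion matrix.

    Folds preserve class proportions to within one sample per class; each
    window is predicted exactly once, by a model not trained on it. The fold
    assignment is a seeded shuffle. Splitting is at the window level, so
    overlapping windows from one bout can land in different folds — the same
    within-individual leakage that inflates window-level cross-validation
    relative to subject-held-out evaluation.
    """
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    thin = labels[counts < k]
    if len(thin):
        raise ValueError(
            f"class {thin[0]!r} has only {int(counts[counts < k][0])} windows; "
            f"need >= {k} for {k}-fold stratification"
        )
    if classes is None:
        order = clf.FINE_CLASSES
        classes = tuple(c for c in order if c in set(labels)) or tuple(sorted(labels))
        extra = sorted(set(labels) - set(classes))
        classes = classes + tuple(extra)
    pred = np.empty(len(y), dtype=object)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = clf.train(X[tr], y[tr], seed=seed + fold + 1, n_trees=n_trees, class_order=classes)
        pred[te] = clf.predict(model, X[te])
    return confusion(y, pred, classes)


def leave_one_subject_out(
    datasets: list[tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
    classes: tuple[str, ...] | None = None,
    n_trees: int = clf.DEFAULT_N_TREES,
) -> ConfusionMatrix:
    """Leave-one-subject-out evaluation over per-subject (X, y) datasets.

    Each subject is predicted by a model trained on all other subjects; the
    pooled confusion matrix estimates performance on unseen individuals.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 subjects")
    all_y = np.concatenate([y for _, y in datasets])
    if classes is None:
        present = set(all_y)
        classes = tuple(c for c in clf.FINE_CLASSES if c in present)
        classes = classes + tuple(sorted(present - set(classes)))
    truth_all, pred_all = [], []
    for i, (X_te, y_te) in enumerate(datasets):
        X_tr = np.vstack([X for j, (X, _) in enumerate(datasets) if j != i])
        y_tr = np.concatenate([y for j, (_, y) in enumerate(datasets) if j != i])
        model = clf.train(X_tr, y_tr, seed=seed + i + 1, n_trees=n_trees, class_order=classes)
        truth_all.append(y_te)
        pred_all.append(clf.predict(model, X_te))
    return confusion(np.concatenate(truth_all), np.concatenate(pred_all), classes)


def metrics_report(cm: ConfusionMatrix) -> dict:
    """JSON-ready report: per-class sensitivity/PPV/F, macro F, sample count."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_class = {
            c: {
                "sensitivity": class_metrics(cm, c).sensitivity,
                "ppv": class_metrics(cm, c).ppv,
                "f_measure": class_metrics(cm, c).f_measure,
            }
            for c in cm.classes
        }
    return {
        "classes": list(cm.classes),
        "per_class": per_class,
        "macro_f": macro_f(cm),
        "n_samples": cm.total,
    }


def write_confusion_csv(cm: ConfusionMatrix, path, comments: list[str] | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write("truth\\pred," + ",".join(cm.classes) + "\n")
        for c, row in zip(cm.classes, cm.counts):
            fh.write(c + "," + ",".join(str(int(v)) for v in row) + "\n")


def read_confusion_csv(path) -> ConfusionMatrix:
    import pandas as pd

    df = pd.read_csv(path, comment="#", index_col=0)
    classes = tuple(df.columns)
    if tuple(df.index) != classes:
        raise ValueError(f"{path}: row and column class orders differ")
    return ConfusionMatrix(classes, df.to_numpy())
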