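"""Confusion-matrix metrics, macro averages, and feature sensitivity analysis.

Per movement class, one-vs-rest counts TP/TN/FP/FN yield

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    efficiency  = (accuracy + sensitivity + specificity) / 3

and the report's macro averages are the unweighted arithmetic means over
classes.  Undefined metrics (empty denominator, e.g. a class absent from the
test set) are reported as NaN and excluded from macro averages with a
warning — never silently zeroed.

The leave-one-feature-out sensitivity analysis retrains the classifier with
each selected feature removed in turn: with Y1 the reference test accuracy
and Y2 the accuracy without feature i, it reports delta = Y2 − Y1 and the
percentage change 100·(Y2 − Y1)/Y1.

Bundled under ``data/reported/`` are per-class performance tables from a
published surface-EMG movement-classification benchmark (lower-limb and
upper-limb databases; GA- and PSO-selected feature sets; training and
validation stages), used as reference values for the metric identities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import SvmModel, SvmSpec, train_ova
from .errors import DataError, ParameterError, ShapeError
from .features import FeatureMatrix, select_columns

REPORTED_TABLES = (
    "leg_ga_train",
    "leg_ga_valid",
    "arm_ga_train",
    "arm_ga_valid",
    "arm_pso_train",
    "arm_pso_valid",
)


@dataclass
class ClassMetrics:
    """One-vs-rest counts and the four derived fractions for one class."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    efficiency: float


def efficiency_from_components(accuracy: float, sensitivity: float, specificity: float) -> float:
    """The benchmark's composite metric: unweighted mean of the three
    component fractions (works on percentages as well)."""
    return (accuracy + sensitivity + specificity) / 3.0


def class_metrics(tp: int, tn: int, fp: int, fn: int) -> ClassMetrics:
    """Evaluate the four metrics from confusion counts.

    Zero denominators yield NaN (undefined), never a silent 0.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ParameterError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise DataError("empty confusion matrix")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    if np.isnan(sensitivity) or np.isnan(specificity):
        warnings.warn("undefined sensitivity/specificity (empty class)", stacklevel=2)
        efficiency = float("nan")
    else:
        efficiency = efficiency_from_components(accuracy, sensitivity, specificity)
    return ClassMetrics(tp, tn, fp, fn, accuracy, sensitivity, specificity, efficiency)


@dataclass
class PerformanceReport:
    """Per-class metrics plus their unweighted macro averages."""

    per_class: dict[str, ClassMetrics]

    def to_frame(self) -> pd.DataFrame:
        rows = {
            cls: {
                "TP": m.tp, "TN": m.tn, "FP": m.fp, "FN": m.fn,
                "accuracy": m.accuracy, "sensitivity": m.sensitivity,
                "specificity": m.specificity, "efficiency": m.efficiency,
            }
            for cls, m in self.per_class.items()
        }
        df = pd.DataFrame(rows).T
        df.index.name = "class"
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                         classes: np.ndarray | None = None) -> PerformanceReport:
    """Build the per-class one-vs-rest report from predicted labels."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ShapeError("y_true and y_pred must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    per_class = {}
    for cls in classes:
        t = y_true == cls
        p = y_pred == cls
        tp = int(np.sum(t & p))
        tn = int(np.sum(~t & ~p))
        fp = int(np.sum(~t & p))
        fn = int(np.sum(t & ~p))
        per_class[str(cls)] = class_metrics(tp, tn, fp, fn)
    return PerformanceReport(per_class=per_class)


def evaluate(model: SvmModel, m: FeatureMatrix) -> PerformanceReport:
    """Predict a labelled matrix with a trained model and report metrics."""
    pred = model.predict(m.values)
    return evaluate_predictions(m.classes, pred, classes=model.class_order)


def macro_average(report: PerformanceReport | pd.DataFrame) -> dict[str, float]:
    """Unweighted mean of each metric over classes, NaN entries excluded
    (with a warning when any are dropped)."""
    df = report.to_frame() if isinstance(report, PerformanceReport) else report
    out = {}
    for metric in ("accuracy", "sensitivity", "specificity", "efficiency"):
        col = df[metric] if metric in df.columns else df.loc[metric]
        vals = np.asarray(col, dtype=float)
        if np.isnan(vals).any():
            warnings.warn(f"{metric}: NaN entries excluded from macro average", stacklevel=2)
        out[metric] = float(np.nanmean(vals))
    return out


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class SensitivityReport:
    """Reference accuracy Y1 and, per removed feature, the accuracy Y2,
    delta = Y2 − Y1 and percentage change 100·(Y2 − Y1)/Y1."""

    y1: float
    table: pd.DataFrame  # columns: channel, predictor, Y1, Y2, delta, pct_change

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _overall_accuracy(model: SvmModel, m: FeatureMatrix) -> float:
    return float(np.mean(model.predict(m.values) == m.classes))


def sensitivity_analysis(
    m_train: FeatureMatrix,
    m_test: FeatureMatrix,
    mask: np.ndarray,
    svm: SvmSpec = SvmSpec(),
) -> SensitivityReport:
    """Leave-one-feature-out retraining over the selected feature set.

    The model is retrained (not column-zeroed) per removal, since removing
    a predictor changes the input dimension the classifier accepts.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 2:
        raise DataError("sensitivity analysis needs at least 2 selected features")
    train_sel = select_columns(m_train, mask)
    test_sel = select_columns(m_test, mask)
    y1 = _overall_accuracy(train_ova(train_sel, svm), test_sel)
    records = []
    for i in range(int(mask.sum())):
        drop = np.ones(int(mask.sum()), dtype=bool)
        drop[i] = False
        model_i = train_ova(select_columns(train_sel, drop), svm)
        y2 = _overall_accuracy(model_i, select_columns(test_sel, drop))
        ch, pred = train_sel.columns[i]
        records.append(
            {
                "channel": ch,
                "predictor": pred,
                "Y1": y1,
                "Y2": y2,
                "delta": y2 - y1,
                "pct_change": 100.0 * (y2 - y1) / y1 if y1 != 0 else float("nan"),
            }
        )
    return SensitivityReport(y1=y1, table=pd.DataFrame(records))


# ---------------------------------------------------------------------------
# bundled reference tables
# ---------------------------------------------------------------------------


def load_reported_table(name: str) -> pd.DataFrame:
    """Load one bundled reference table (percent units).

    Rows: sensitivity, specificity, accuracy, efficiency; columns: movement
    classes.  Valid names: leg_ga_train, leg_ga_valid, arm_ga_train,
    arm_ga_valid, arm_pso_train, arm_pso_valid.
    """
    if name not in REPORTED_TABLES:
        raise ParameterError(f"unknown table {name!r}; valid: {REPORTED_TABLES}")
    ref = resources.files("emgselect").joinpath(f"data/reported/{name}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, index_col=0)
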