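"""Confusion-matrix metrics, session aggregation, channel ablation and tables.

Metrics follow the usual one-vs-rest reduction of a K-class confusion
matrix: for each class c, with TP/FP/FN/TN read off the matrix,

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)        (sensitivity)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * recall / (precision + recall)

Macro metrics are unweighted means over the three classes; 0/0 cells (an
empty predicted or actual class) are defined as 0 and flagged so reports
stay total. ``overall_accuracy`` is the plain trace / total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import LABELS, canonical_order

__all__ = [
    "ConfusionMatrixError",
    "EvalReport",
    "AggregateReport",
    "confusion",
    "metrics",
    "aggregate_reports",
    "run_ablation",
    "report_tables",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


class ConfusionMatrixError(ValueError):
    pass


def confusion(y_true, y_pred, n_classes: int = 3) -> np.ndarray:
    """K x K counts; entry (i, j) = actual class i predicted as class j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ConfusionMatrixError("y_true and y_pred must be equal-length 1-D arrays")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ConfusionMatrixError(f"{name} contains labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_div(num: float, den: float, flags: list, what: str) -> float:
    if den == 0:
        flags.append(f"{what}: 0/0 reported as 0")
        return 0.0
    return num / den


@dataclass
class EvalReport:
    """Per-class and macro metrics for one confusion matrix."""

    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    overall_accuracy: float
    flags: list[str] = field(default_factory=list)


def metrics(cm: np.ndarray) -> EvalReport:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ConfusionMatrixError(f"confusion matrix must be square, got {cm.shape}")
    if np.any(cm < 0):
        raise ConfusionMatrixError("confusion matrix entries must be non-negative")
    total = int(cm.sum())
    if total == 0:
        raise ConfusionMatrixError("empty confusion matrix")
    k = cm.shape[0]
    flags: list[str] = []
    per_class = {}
    for c in range(k):
        name = LABELS[c] if k == len(LABELS) else f"class_{c}"
        tp = int(cm[c, c])
        fp = int(cm[:, c].sum() - tp)
        fn = int(cm[c, :].sum() - tp)
        tn = total - tp - fp - fn
        precision = _safe_div(tp, tp + fp, flags, f"{name}.precision")
        recall = _safe_div(tp, tp + fn, flags, f"{name}.recall")
        per_class[name] = {
            "accuracy": (tp + tn) / total,
            "precision": precision,
            "recall": recall,
            "sensitivity": recall,
            "specificity": _safe_div(tn, tn + fp, flags, f"{name}.specificity"),
            "f1": _safe_div(2 * precision * recall, precision + recall, flags, f"{name}.f1"),
        }
    macro = {
        m: float(np.mean([per_class[n][m] for n in per_class]))
        for m in ("accuracy", "precision", "recall", "sensitivity", "specificity", "f1")
    }
    return EvalReport(
        confusion=cm.astype(int),
        per_class=per_class,
        macro=macro,
        overall_accuracy=float(np.trace(cm) / total),
        flags=flags,
    )


@dataclass
class AggregateReport:
    """Mean +/- sd of metrics across training sessions.

    ``accuracy`` aggregates the overall (trace/total) accuracy; the other
    four metrics aggregate the macro-averaged one-vs-rest values, matching
    the single-scalar-per-metric reporting convention.
    """

    n_sessions: int
    mean: dict[str, float]
    sd: dict[str, float]
    reports: list[EvalReport] = field(default_factory=list)

    def cell(self, metric: str) -> str:
        return f"{self.mean[metric]:.3f} ± {self.sd[metric]:.3f}"

    def as_row(self) -> dict[str, str]:
        return {m: self.cell(m) for m in METRIC_NAMES}


def aggregate_reports(reports: list[EvalReport]) -> AggregateReport:
    if not reports:
        raise ValueError("no reports to aggregate")

    def series(metric):
        if metric == "accuracy":
            return np.array([r.overall_accuracy for r in reports])
        return np.array([r.macro[metric] for r in reports])

    mean = {m: float(series(m).mean()) for m in METRIC_NAMES}
    sd = {m: float(series(m).std(ddof=0)) for m in METRIC_NAMES}
    return AggregateReport(n_sessions=len(reports), mean=mean, sd=sd, reports=reports)


def run_ablation(
    recordings,
    subsets,
    model_config,
    train_config,
    split_spec,
    mfcc_params=None,
    log=None,
) -> dict[tuple[str, ...], AggregateReport]:
    """Retrain and evaluate per position subset, isolating channel count.

    The subject-level split is computed ONCE on the full recordings and
    reused for every subset, and every subset's ensemble starts from the
    same base seed, so the only thing that varies between rows is which
    channels the features were built from. Duplicate subsets (after
    canonical ordering) are evaluated once.
    """
    from .training import prepare_inputs, split, train_ensemble  # cycle guard

    unique: list[tuple[str, ...]] = []
    for sub in subsets:
        key = tuple(canonical_order(sub))
        if key not in unique:
            unique.append(key)
    for key in unique:
        missing = [p for p in key if p not in recordings[0].positions]
        if missing:
            raise ValueError(f"subset {key} requests positions {missing} absent from the cohort")

    tr, va, te = split(recordings, split_spec)
    results: dict[tuple[str, ...], AggregateReport] = {}
    for key in unique:
        if log is not None:
            log(f"ablation subset {'-'.join(key)} ({len(key)} ch.)")
        parts = [
            prepare_inputs(
                [rec.subset(key) for rec in part],
                input_kind=model_config.input_kind,
                params=mfcc_params,
            )
            for part in (tr, va, te)
        ]
        *_, agg = train_ensemble(model_config, parts[0], parts[1], parts[2], train_config, log=log)
        results[key] = agg
    return results


def report_tables(
    result: dict[tuple[str, ...], AggregateReport], out_dir
) -> tuple[Path, Path]:
    """Write the ablation grid as CSV and an aligned text table.

    One row per position subset; metric cells are "mean +/- sd" strings.
    Returns the (csv, txt) paths.
    """
    if not result:
        raise ValueError("empty ablation result")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for key, agg in result.items():
        row = {"positions": "-".join(key), "n_channels": len(key)}
        row.update(agg.as_row())
        rows.append(row)
    df = pd.DataFrame(rows)
    csv_path = out_dir / "ablation.csv"
    txt_path = out_dir / "ablation.txt"
    df.to_csv(csv_path, index=False)
    txt_path.write_text(df.to_string(index=False) + "\n")
    return csv_path, txt_path
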