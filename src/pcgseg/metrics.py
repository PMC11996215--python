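"""Per-sample evaluation panel: Acc, Se, P+, Sp, F1 over the four phases.

Every signal sample is scored (no tolerance windows around onsets).  Per
class c, counted one-vs-rest from the 4x4 confusion matrix:

    Se  = TP / (TP + FN)            sensitivity (recall)
    Sp  = TN / (TN + FP)            specificity
    P+  = TP / (TP + FP)            precision (positive predictivity)
    F1  = 2 * P+ * Se / (P+ + Se)

The single summary row per group macro-averages these over the four
classes, while overall accuracy is micro (trace / total).  A class that
never occurs leaves its metrics undefined; undefined values are reported as
missing and excluded from macro means rather than silently scored 0 or 100.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CLASSES, LabelSequence, SegmentDataset

#: Report column order.
METRIC_COLUMNS = ("Acc", "Se", "P+", "Sp", "F1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """4x4 count table; rows are true classes, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        n = len(CLASSES)
        if counts.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class MetricReport:
    """Per-class and macro metrics (percent) for one evaluation group."""

    group: str
    accuracy: float  # micro: trace / total, percent
    per_class: dict[str, dict[str, float | None]]
    macro: dict[str, float | None]
    n_samples: int
    confusion: ConfusionMatrix | None = field(default=None, repr=False)

    def row(self) -> dict[str, float | None]:
        """Summary row in the panel's column order."""
        return {
            "Acc": self.accuracy,
            "Se": self.macro["Se"],
            "P+": self.macro["P+"],
            "Sp": self.macro["Sp"],
            "F1": self.macro["F1"],
        }


def confusion(truth: LabelSequence, pred: LabelSequence) -> ConfusionMatrix:
    """Count (true, predicted) label pairs."""
    t = truth.labels
    p = pred.labels
    if t.size != p.size:
        raise ValueError(f"length mismatch: truth {t.size}, prediction {p.size}")
    n = len(CLASSES)
    counts = np.bincount(t * n + p, minlength=n * n).reshape(n, n)
    return ConfusionMatrix(counts)


def confusion_from_codes(truth: np.ndarray, pred: np.ndarray) -> ConfusionMatrix:
    rate = 1
    return confusion(
        LabelSequence(np.ravel(truth), rate), LabelSequence(np.ravel(pred), rate)
    )


def _safe_ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def score(cm: ConfusionMatrix, group: str = "ALL") -> MetricReport:
    """Compute the metric panel from a confusion matrix.

    Metrics are scale-invariant (multiplying all counts by k changes
    nothing) and classes with zero denominators yield ``None``.
    """
    c = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, dict[str, float | None]] = {}
    for k, name in enumerate(CLASSES):
        tp = float(c[k, k])
        fn = float(c[k].sum() - tp)
        fp = float(c[:, k].sum() - tp)
        tn = float(total - tp - fn - fp)
        se = _safe_ratio(tp, tp + fn)
        sp = _safe_ratio(tn, tn + fp)
        pp = _safe_ratio(tp, tp + fp)
        if se is None or pp is None or (se + pp) == 0:
            f1 = None
        else:
            f1 = 2.0 * pp * se / (pp + se)
        per_class[name] = {
            "Acc": _safe_ratio(tp + tn, total),
            "Se": se,
            "Sp": sp,
            "P+": pp,
            "F1": f1,
        }
    macro = {}
    for m in ("Acc", "Se", "Sp", "P+", "F1"):
        vals = [per_class[name][m] for name in CLASSES if per_class[name][m] is not None]
        macro[m] = float(np.mean(vals)) if vals else None
    return MetricReport(
        group=group,
        accuracy=100.0 * float(np.trace(c)) / total,
        per_class=per_class,
        macro=macro,
        n_samples=total,
        confusion=cm,
    )


def evaluate(
    model,
    dataset: SegmentDataset,
    group_by: str = "site",
) -> list[MetricReport]:
    """Score a trained model per group plus a pooled ``ALL`` row.

    ``group_by`` is ``"site"`` or ``"record"``.  The ``ALL`` row is computed
    from the pooled confusion matrix, not by averaging group metrics, so its
    accuracy is the sample-weighted (micro) aggregate.
    """
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    if group_by == "site":
        keys = dataset.sites
    elif group_by == "record":
        keys = dataset.source_ids
    else:
        raise ValueError("group_by must be 'site' or 'record'")
    pred = model.predict_batch(dataset.features)
    groups: dict[str, ConfusionMatrix] = {}
    for i, key in enumerate(keys):
        cm = confusion_from_codes(dataset.labels[i], pred[i])
        groups[key] = groups[key] + cm if key in groups else cm
    reports = [score(cm, group=key) for key, cm in groups.items()]
    pooled = ConfusionMatrix(sum(cm.counts for cm in groups.values()))
    reports.append(score(pooled, group="ALL"))
    return reports


def reports_to_frame(reports: list[MetricReport]) -> pd.DataFrame:
    """Summary table with one row per group, columns Acc, Se, P+, Sp, F1."""
    rows = []
    for r in reports:
        row = {"group": r.group, "n": r.n_samples}
        row.update(r.row())
        rows.append(row)
    return pd.DataFrame(rows, columns=["group", "n", *METRIC_COLUMNS])


def write_reports(path: str | Path, reports: list[MetricReport]) -> None:
    """Write the panel as TSV plus a JSON sidecar with per-class detail."""
    path = Path(path)
    frame = reports_to_frame(reports)
    frame.to_csv(path.with_suffix(".tsv"), sep="\t", index=False, float_format="%.2f")
    detail = [
        {
            "group": r.group,
            "n_samples": r.n_samples,
            "accuracy": r.accuracy,
            "macro": r.macro,
            "per_class": r.per_class,
        }
        for r in reports
    ]
    path.with_suffix(".json").write_text(json.dumps(detail, indent=2))


def held_out_accuracy(model, dataset: SegmentDataset) -> float:
    """Per-sample accuracy (percent) of a model on its held-out records."""
    test_ids = set(model.test_record_ids)
    idx = [i for i, sid in enumerate(dataset.source_ids) if sid in test_ids]
    if not idx:
        raise ValueError("dataset contains no segments from the model's held-out records")
    sub = dataset.subset(idx)
    pred = model.predict_batch(sub.features)
    return 100.0 * float(np.mean(pred == sub.labels))


def macro_f1(model, dataset: SegmentDataset) -> float:
    """Macro-averaged F1 (percent) over a whole dataset."""
    pred = model.predict_batch(dataset.features)
    cm = confusion_from_codes(dataset.labels, pred)
    f1 = score(cm).macro["F1"]
    return float("nan") if f1 is None else float(f1)
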