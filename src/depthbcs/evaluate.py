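"""Tolerance-band evaluation: accuracy, per-class and weighted P/R/F1.

BCS evaluation is ordinal: a prediction is also scored under tolerance
bands of one grid step (within 0.25 BCS) and two steps (within 0.5 BCS).
Tolerance is applied by *relabeling*: a prediction inside the band is
scored as the true class before the confusion matrix is built. Under this
convention the class-weighted recall equals the band accuracy (the micro
identity), which is the convention consistent with published BCS tables.

Per class c: Precision = TP/(TP+FP), Recall = TP/(TP+FN),
F1 = 2PR/(P+R); weighted metric = sum_c W_c * metric_c with
W_c = n_c / N. Zero denominators yield 0. Percentages are reported to
2 decimal places, half-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .depth_io import BCS_GRID

__all__ = [
    "ToleranceBand", "ConfusionMatrix", "MetricsReport", "EvaluationError",
    "relabel_within_tolerance", "accuracy", "confusion_matrix",
    "class_metrics", "weighted_metrics", "f1_score", "weighted_average",
    "evaluate_predictions",
    "evaluate_model", "render_report_table", "BAND_NAMES",
    "save_predictions", "load_predictions",
]

N_CLASSES = len(BCS_GRID)

BAND_NAMES = {0: "Exact BCS", 1: "Within 0.25 BCS", 2: "Within 0.5 BCS"}


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ToleranceBand:
    """0 = exact, 1 = within 0.25 BCS (one step), 2 = within 0.5 BCS."""

    steps: int

    def __post_init__(self) -> None:
        if self.steps not in (0, 1, 2):
            raise EvaluationError("tolerance band must be 0, 1 or 2 steps")

    @property
    def bcs_tolerance(self) -> float:
        return self.steps * 0.25


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def _check_classes(*arrays: np.ndarray) -> list[np.ndarray]:
    out = []
    n = None
    for a in arrays:
        a = np.asarray(a, dtype=np.int64)
        if a.ndim != 1:
            raise EvaluationError("class arrays must be 1-D")
        if n is None:
            n = len(a)
        elif len(a) != n:
            raise EvaluationError("true/predicted lengths differ")
        if len(a) and (a.min() < 0 or a.max() >= N_CLASSES):
            raise EvaluationError(f"class indices outside 0..{N_CLASSES - 1}")
        out.append(a)
    return out


def relabel_within_tolerance(true: np.ndarray, predicted: np.ndarray,
                             band: ToleranceBand) -> np.ndarray:
    """Score predictions inside the band as the true class."""
    true, predicted = _check_classes(true, predicted)
    inside = np.abs(predicted - true) <= band.steps
    return np.where(inside, true, predicted)


def accuracy(true: np.ndarray, adjusted: np.ndarray) -> float:
    """Percentage of correct estimations."""
    true, adjusted = _check_classes(true, adjusted)
    if len(true) == 0:
        raise EvaluationError("cannot score an empty prediction set")
    return 100.0 * float(np.mean(true == adjusted))


@dataclass
class ConfusionMatrix:
    counts: np.ndarray    # rows = true class, columns = predicted class

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (N_CLASSES, N_CLASSES) or (c < 0).any():
            raise EvaluationError(f"confusion matrix must be non-negative "
                                  f"{N_CLASSES}x{N_CLASSES}")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()

    def class_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def confusion_matrix(true: np.ndarray, predicted: np.ndarray) -> ConfusionMatrix:
    true, predicted = _check_classes(true, predicted)
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(counts, (true, predicted), 1)
    return ConfusionMatrix(counts)


def class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision/recall/F1 in percent (0 on zero denominators)."""
    tp, fp, fn = cm.tp().astype(float), cm.fp().astype(float), cm.fn().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return pd.DataFrame({
        "bcs": BCS_GRID,
        "precision": 100 * prec,
        "recall": 100 * rec,
        "f1": 100 * f1,
        "n": cm.class_counts(),
    })


def weighted_metrics(per_class: pd.DataFrame,
                     class_counts: np.ndarray | None = None) -> dict[str, float]:
    """Class-weighted averages with W_c = n_c / N."""
    counts = np.asarray(per_class["n"] if class_counts is None else class_counts,
                        dtype=float)
    if counts.sum() <= 0:
        raise EvaluationError("zero total count")
    w = counts / counts.sum()
    return {m: float(np.sum(w * np.asarray(per_class[m], dtype=float)))
            for m in ("precision", "recall", "f1")}


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same units as its inputs)."""
    if precision + recall <= 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def weighted_average(values, counts) -> float:
    """Class-weighted average with W_c = n_c / N."""
    v = np.asarray(values, dtype=float)
    n = np.asarray(counts, dtype=float)
    if n.sum() <= 0:
        raise EvaluationError("zero total count")
    return float(np.sum(v * n / n.sum()))


@dataclass
class MetricsReport:
    """Per-band metrics for one camera-set model."""

    name: str
    bands: dict[int, dict] = field(default_factory=dict)

    def add_band(self, band: ToleranceBand, acc: float,
                 per_class: pd.DataFrame, weighted: dict[str, float]) -> None:
        self.bands[band.steps] = {
            "accuracy": _round2(acc),
            "per_class": per_class,
            "weighted": {k: _round2(v) for k, v in weighted.items()},
        }

    def accuracy(self, steps: int) -> float:
        return self.bands[steps]["accuracy"]

    def to_dict(self) -> dict:
        out = {"name": self.name, "bands": {}}
        for steps, entry in self.bands.items():
            pc = entry["per_class"]
            out["bands"][BAND_NAMES[steps]] = {
                "accuracy": entry["accuracy"],
                "weighted": entry["weighted"],
                "per_class": {
                    f"{row.bcs:.2f}": {
                        "precision": _round2(row.precision),
                        "recall": _round2(row.recall),
                        "f1": _round2(row.f1),
                        "n": int(row.n),
                    } for row in pc.itertuples()
                },
            }
        return out


def evaluate_predictions(true: np.ndarray, predicted: np.ndarray,
                         bands: tuple[int, ...] = (0, 1, 2),
                         name: str = "model") -> MetricsReport:
    """Full tolerance-band report: relabel -> confusion -> metrics per band."""
    true, predicted = _check_classes(true, predicted)
    if len(true) == 0:
        raise EvaluationError("cannot evaluate an empty prediction set")
    report = MetricsReport(name=name)
    for steps in bands:
        band = ToleranceBand(steps)
        adjusted = relabel_within_tolerance(true, predicted, band)
        cm = confusion_matrix(true, adjusted)
        pc = class_metrics(cm)
        report.add_band(band, accuracy(true, adjusted), pc, weighted_metrics(pc))
    return report


def evaluate_model(prediction_records, bands: tuple[int, ...] = (0, 1, 2),
                   name: str = "model") -> MetricsReport:
    """Report from a list of PredictionRecord objects."""
    true = np.array([r.true_class for r in prediction_records])
    pred = np.array([r.predicted_class for r in prediction_records])
    return evaluate_predictions(true, pred, bands=bands, name=name)


def save_predictions(records, camera_set: str, path) -> None:
    """Persist prediction records as CSV (cow_id,true_bcs,camera_set,p0..p7,pred_bcs)."""
    rows = []
    for r in records:
        row = {"cow_id": r.cow_id,
               "true_bcs": f"{BCS_GRID[r.true_class]:.2f}",
               "camera_set": camera_set}
        for k in range(N_CLASSES):
            row[f"p{k}"] = float(r.fused[k])
        row["pred_bcs"] = f"{BCS_GRID[r.predicted_class]:.2f}"
        rows.append(row)
    cols = ["cow_id", "true_bcs", "camera_set"] + \
        [f"p{k}" for k in range(N_CLASSES)] + ["pred_bcs"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def load_predictions(path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """(true classes, predicted classes, full table) from a predictions CSV."""
    df = pd.read_csv(path)
    true = np.array([BCS_GRID.index(round(float(v), 2)) for v in df["true_bcs"]])
    pred = np.array([BCS_GRID.index(round(float(v), 2)) for v in df["pred_bcs"]])
    return true, pred, df


def render_report_table(reports: list[MetricsReport],
                        bands: tuple[int, ...] = (0, 1, 2)) -> str:
    """Text table: one row per camera-set model, one accuracy column per band."""
    headers = ["Approach"] + [BAND_NAMES[b] + " (%)" for b in bands]
    rows = [[r.name] + [f"{r.accuracy(b):.2f}" for b in bands] for r in reports]
    widths = [max(len(h), *(len(row[i]) for row in rows))
              for i, h in enumerate(headers)]
    def fmt(row):
        return "  ".join(cell.ljust(w) for cell, w in zip(row, widths))
    lines = [fmt(headers), fmt(["-" * w for w in widths])]
    lines += [fmt(row) for row in rows]
    return "\n".join(lines)
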