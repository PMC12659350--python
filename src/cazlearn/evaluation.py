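"""Benchmarking harness: binary tallies, family confusion, ROC / PR curves.

The binary metrics follow the standard definitions

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with the 0/0 convention resolved to 0 so degenerate classes stay scorable.
Family assignment quality is summarised by a K x K confusion matrix and the
micro-averaged accuracy (total correct over total, pooling classes).

ROC and precision-recall curves are built from score files — either the
gate's vote fractions (larger = more CAZyme-like) or a homology tool's
e-values (smaller = stronger hit); ``larger_is_positive`` declares the
polarity.  Queries missing from a third-party hit file can be imputed the
worst possible score so every curve is computed over the full truth set.
One curve point is emitted per distinct score value (ties grouped), which
matches an exhaustive sweep over all thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .curation import FamilyOntology


class EvaluationError(ValueError):
    """Raised on invalid benchmarking inputs."""


@dataclass(frozen=True)
class BinaryTally:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("tally counts must be non-negative")


def precision_recall_f1(t: BinaryTally) -> tuple[float, float, float]:
    """Precision, recall and F1 from a tally; empty denominators give 0."""
    precision = t.tp / (t.tp + t.fp) if (t.tp + t.fp) else 0.0
    recall = t.tp / (t.tp + t.fn) if (t.tp + t.fn) else 0.0
    f1 = (
        2.0 * recall * precision / (recall + precision)
        if (recall + precision)
        else 0.0
    )
    return precision, recall, f1


def tally_binary(
    predicted: Sequence[bool], truth: Sequence[bool]
) -> BinaryTally:
    if len(predicted) != len(truth):
        raise EvaluationError("predicted and truth must align")
    p = np.asarray(predicted, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    return BinaryTally(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def confusion_and_micro_accuracy(
    predicted, truth, ontology: FamilyOntology
) -> tuple[np.ndarray, float]:
    """K x K confusion matrix (rows = true, cols = predicted) and micro
    accuracy = trace / total."""
    if len(predicted) != len(truth):
        raise EvaluationError("predicted and truth label lists must align")
    if len(truth) == 0:
        raise EvaluationError("cannot score an empty label list")
    K = ontology.K
    mat = np.zeros((K, K), dtype=int)
    for t, p in zip(truth, predicted):
        mat[ontology.index_of(t), ontology.index_of(p)] += 1
    return mat, float(np.trace(mat) / mat.sum())


@dataclass
class CurvePoints:
    """Curve points as (threshold, x, y) triples, thresholds decreasing.

    For ROC x is the false-positive rate and y the true-positive rate; for
    precision-recall x is recall and y precision.
    """

    points: list[tuple[float, float, float]]

    @property
    def thresholds(self) -> list[float]:
        return [p[0] for p in self.points]

    @property
    def xs(self) -> list[float]:
        return [p[1] for p in self.points]

    @property
    def ys(self) -> list[float]:
        return [p[2] for p in self.points]


def roc_pr_curves(
    scores: Mapping[str, float],
    truth: Mapping[str, bool],
    larger_is_positive: bool = True,
    impute_missing: bool = True,
) -> tuple[CurvePoints, CurvePoints, float, float]:
    """Build ROC and PR curves and their areas from a score file.

    Every id in ``truth`` is scored; ids absent from ``scores`` are imputed
    the worst score (never called positive) when ``impute_missing`` is set,
    and are an error otherwise.  Returns (roc, pr, auroc, aupr); both areas
    by trapezoid over the enumerated points.
    """
    ids = list(truth)
    if not ids:
        raise EvaluationError("empty truth set")
    y = np.array([bool(truth[i]) for i in ids])
    if y.all() or not y.any():
        raise EvaluationError("truth must contain both positives and negatives")

    sign = 1.0 if larger_is_positive else -1.0
    missing = [i for i in ids if i not in scores]
    if missing and not impute_missing:
        raise EvaluationError(f"no score for id(s): {missing[:5]}")
    finite = [sign * scores[i] for i in ids if i in scores]
    worst = (min(finite) if finite else 0.0) - 1.0
    s = np.array([sign * scores[i] if i in scores else worst for i in ids])

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos

    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(~y_sorted)
    # one point per distinct score value: take the last index of each group
    distinct_last = np.nonzero(np.diff(s_sorted, append=np.nan))[0]

    roc_pts: list[tuple[float, float, float]] = [(np.inf, 0.0, 0.0)]
    pr_pts: list[tuple[float, float, float]] = [(np.inf, 0.0, 1.0)]
    for idx in distinct_last:
        thr = float(s_sorted[idx])
        tp, fp = int(tp_cum[idx]), int(fp_cum[idx])
        roc_pts.append((thr, fp / n_neg, tp / n_pos))
        pr_pts.append((thr, tp / n_pos, tp / (tp + fp)))

    roc = CurvePoints(roc_pts)
    pr = CurvePoints(pr_pts)
    auroc = float(np.trapezoid([p[2] for p in roc_pts], [p[1] for p in roc_pts]))
    aupr = float(np.trapezoid([p[2] for p in pr_pts], [p[1] for p in pr_pts]))
    return roc, pr, auroc, aupr


def write_curve_tsv(curve: CurvePoints, path, x_name: str = "x", y_name: str = "y") -> None:
    with open(path, "w") as fh:
        fh.write(f"threshold\t{x_name}\t{y_name}\n")
        for thr, x, y in curve.points:
            fh.write(f"{thr:.6g}\t{x:.6f}\t{y:.6f}\n")


def write_metrics_tsv(report: dict[str, dict[str, float]], path) -> None:
    """Per-class metrics table (one row per label, plus a macro-average row)."""
    cols = ["precision", "recall", "f1", "support"]
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(cols) + "\n")
        for label, row in report.items():
            fh.write(label + "\t" + "\t".join(f"{row[c]:.6g}" for c in cols) + "\n")
        if report:
            macro = {c: float(np.mean([r[c] for r in report.values()])) for c in cols[:3]}
            fh.write(
                "macro_avg\t"
                + "\t".join(f"{macro[c]:.6g}" for c in cols[:3])
                + f"\t{sum(r['support'] for r in report.values()):.6g}\n"
            )


def per_class_report(
    predicted, truth, ontology: FamilyOntology
) -> dict[str, dict[str, float]]:
    """One-vs-rest precision / recall / F1 per ontology label."""
    report: dict[str, dict[str, float]] = {}
    for lab in ontology.labels:
        t = tally_binary([p == lab for p in predicted], [x == lab for x in truth])
        prec, rec, f1 = precision_recall_f1(t)
        report[str(lab)] = {
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "support": t.tp + t.fn,
        }
    return report
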