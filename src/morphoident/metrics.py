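"""Rank-based scoring of identifier output.

A collection is of rank K if the identifier assigned its true class the
K-th highest probability.  From the ranks of a testing set we report:

* Top-N — the proportion of collections with rank <= N (N = 1, 3, 5);
* MRR — the mean of reciprocal ranks, 1 when every collection is rank 1;
* macro-averaged F1 — the unweighted mean of per-class F1 scores, which
  removes the bias toward abundant classes in a heavily imbalanced genus.

Ties are resolved pessimistically: when the true class's probability is
tied with others, the true class is ranked after every tied competitor, so
reported scores are conservative and deterministic.  Macro-F1 averages over
the classes the testing set can actually measure — those with at least one
true collection; classes that appear only as false-positive predictions are
listed in the per-class table (their F1 is 0) but are not averaged, and
classes absent from both truth and predictions are excluded entirely.  P, R
or F1 with a zero denominator count as 0.  Values are reported on both the
0-1 scale and the /100 scale of the result tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np

from .identifier import Prediction, predict

if TYPE_CHECKING:  # pragma: no cover
    from .dataset import CollectionRecord
    from .model import CalibratedIdentifier

__all__ = [
    "PredictionRecord",
    "MetricReport",
    "rank_of",
    "top_n",
    "mrr",
    "macro_f1",
    "evaluate",
    "mrr_from_probs",
]


@dataclass(frozen=True)
class PredictionRecord:
    """A true class paired with the full ordered probability vector."""

    true_class: str
    prediction: Prediction

    def __post_init__(self) -> None:
        if self.true_class not in self.prediction.classes:
            raise ValueError(f"true class {self.true_class!r} not among predicted classes")


def _rank_pessimistic(probs: np.ndarray, true_idx: int) -> int:
    pt = probs[true_idx]
    higher = int((probs > pt).sum())
    tied_others = int((probs == pt).sum()) - 1
    return 1 + higher + tied_others


def rank_of(record: PredictionRecord) -> int:
    """Rank of the true class, 1 = top guess; ties count against the truth."""
    idx = record.prediction.classes.index(record.true_class)
    return _rank_pessimistic(record.prediction.probabilities, idx)


def _ranks(records: Sequence[PredictionRecord]) -> np.ndarray:
    if not records:
        raise ValueError("empty record set")
    return np.array([rank_of(r) for r in records])


def top_n(records: Sequence[PredictionRecord], n: int) -> float:
    """Proportion of collections with rank <= n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    r = _ranks(records)
    return float((r <= n).mean())


def mrr(records: Sequence[PredictionRecord]) -> float:
    """Mean reciprocal rank over the record set."""
    return float((1.0 / _ranks(records)).mean())


def mrr_from_probs(probs: np.ndarray, true_indices: Sequence[int]) -> float:
    """MRR straight from a probability matrix (used for model selection)."""
    true_indices = np.asarray(true_indices, dtype=int)
    if len(true_indices) == 0:
        raise ValueError("empty record set")
    ranks = np.array(
        [_rank_pessimistic(row, t) for row, t in zip(np.asarray(probs), true_indices)]
    )
    return float((1.0 / ranks).mean())


def _top1_label(record: PredictionRecord) -> str:
    """Top-1 predicted class under the pessimistic tie rule.

    Among classes tied at the maximum probability the true class loses to
    any competitor; otherwise ties break by class-list order.
    """
    p = record.prediction.probabilities
    top = np.flatnonzero(p == p.max())
    classes = record.prediction.classes
    labels = [classes[i] for i in top]
    if len(labels) > 1:
        others = [c for c in labels if c != record.true_class]
        if others:
            return others[0]
    return labels[0]


def macro_f1(
    records: Sequence[PredictionRecord],
) -> tuple[float, list[dict]]:
    """Macro-averaged F1 plus the per-class confusion table.

    The average runs over classes with at least one true collection in the
    record set; classes seen only as false positives are tabulated but not
    averaged.
    """
    if not records:
        raise ValueError("empty record set")
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    confused: dict[str, dict[str, int]] = {}
    for rec in records:
        pred = _top1_label(rec)
        truth = rec.true_class
        if pred == truth:
            tp[truth] = tp.get(truth, 0) + 1
        else:
            fp[pred] = fp.get(pred, 0) + 1
            fn[truth] = fn.get(truth, 0) + 1
            confused.setdefault(truth, {})[pred] = (
                confused.setdefault(truth, {}).get(pred, 0) + 1
            )
    measured = sorted(set(tp) | set(fp) | set(fn))
    per_class: list[dict] = []
    f1s = []
    for cls in measured:
        t, f_p, f_n = tp.get(cls, 0), fp.get(cls, 0), fn.get(cls, 0)
        precision = t / (t + f_p) if t + f_p else 0.0
        recall = t / (t + f_n) if t + f_n else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        worst = max(confused.get(cls, {}), key=confused.get(cls, {}).get, default="")
        per_class.append(
            {
                "class": cls,
                "TP": t,
                "FP": f_p,
                "FN": f_n,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "confused_as": worst,
            }
        )
        if t + f_n > 0:  # class measurable: it has true instances
            f1s.append(f1)
    return float(np.mean(f1s)), per_class


@dataclass
class MetricReport:
    """All metrics of one evaluation, on the 0-1 scale."""

    n: int
    top1: float
    top3: float
    top5: float
    mrr: float
    macro_f1: float
    per_class: list[dict]

    def scaled(self) -> dict[str, float]:
        """The /100 presentation used in the result tables."""
        return {
            "n": self.n,
            "top1": round(100 * self.top1, 1),
            "top3": round(100 * self.top3, 1),
            "top5": round(100 * self.top5, 1),
            "mrr": round(100 * self.mrr, 1),
            "macro_f1": round(100 * self.macro_f1, 1),
        }

    def to_tsv(self, path: str | Path) -> None:
        lines = ["metric\tvalue\tvalue_out_of_100"]
        scaled = self.scaled()
        for key in ("top1", "top3", "top5", "mrr", "macro_f1"):
            lines.append(f"{key}\t{getattr(self, key):.6f}\t{scaled[key]}")
        lines.append(f"n\t{self.n}\t{self.n}")
        lines.append("")
        lines.append("class\tTP\tFP\tFN\tprecision\trecall\tf1\tconfused_as")
        for row in self.per_class:
            lines.append(
                f"{row['class']}\t{row['TP']}\t{row['FP']}\t{row['FN']}\t"
                f"{row['precision']:.4f}\t{row['recall']:.4f}\t{row['f1']:.4f}\t"
                f"{row['confused_as']}"
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def score(records: Sequence[PredictionRecord]) -> MetricReport:
    """Compute every metric over one set of prediction records."""
    f1, per_class = macro_f1(records)
    return MetricReport(
        n=len(records),
        top1=top_n(records, 1),
        top3=top_n(records, 3),
        top5=top_n(records, 5),
        mrr=mrr(records),
        macro_f1=f1,
        per_class=per_class,
    )


def evaluate(
    target: "CalibratedIdentifier | Callable[[CollectionRecord], Prediction]",
    test_records: Sequence["CollectionRecord"],
    true_labels: Sequence[str] | None = None,
    taxonomy=None,
) -> MetricReport:
    """Score an identifier (or any record -> Prediction callable) on a test set.

    True labels default to the records' species labels; for a section-mode
    identifier pass the taxonomy so species labels are mapped to sections.
    """
    if not test_records:
        raise ValueError("empty test set")
    if callable(target) and not hasattr(target, "predict_proba"):
        predict_fn = target
        mode = "species"
    else:
        predict_fn = lambda r: predict(target, r)  # noqa: E731
        mode = getattr(target, "mode", "species")
    records: list[PredictionRecord] = []
    for i, rec in enumerate(test_records):
        if true_labels is not None:
            truth = true_labels[i]
        else:
            truth = rec.species
            if truth is None:
                raise ValueError(f"collection {rec.collection_id!r} has no label")
            if mode == "section":
                if taxonomy is None:
                    raise ValueError("section-mode evaluation needs a taxonomy")
                truth = taxonomy.section_of(truth)
        records.append(PredictionRecord(truth, predict_fn(rec)))
    return score(records)
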