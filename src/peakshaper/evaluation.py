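"""Labeled-region evaluation of peak calls.

Each labeled region is judged independently against the calls passing the
score threshold: a labeled peak overlapped by >= 1 bp of any passing call is
a true positive (else false negative); a labeled noise region overlapped by
any passing call is a false positive (else true negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from peakshaper.coverage_io import GenomicRegion
from peakshaper.model import ScoredPeak


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    selectivity: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": self.precision, "recall": self.recall,
            "selectivity": self.selectivity, "f1": self.f1,
        }


def _overlaps(a: GenomicRegion, b: GenomicRegion) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def evaluate(
    calls: Sequence[ScoredPeak],
    labels: Iterable[tuple[GenomicRegion, str]],
    threshold: float = 0.5,
) -> EvaluationReport:
    """Score calls against peak/noise labeled regions at a Peak-Score threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    labels = list(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    passing = [c.region for c in calls if c.peak_score >= threshold]
    tp = fp = tn = fn = 0
    for region, cls in labels:
        hit = any(_overlaps(region, r) for r in passing)
        if cls == "peak":
            tp += hit
            fn += not hit
        elif cls == "noise":
            fp += hit
            tn += not hit
        else:
            raise ValueError(f"unknown label class {cls!r}")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    selectivity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvaluationReport(tp, fp, tn, fn, precision, recall, selectivity, f1)
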