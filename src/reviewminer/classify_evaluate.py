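"""Multi-label topic assignment via the 1/L rule and its evaluation.

A trained topic model gives every review a distribution theta over the L
taxonomy labels.  A label is assigned when its probability strictly exceeds
1/L — the uniform-baseline threshold — so a uniform row yields no labels (a
reportable outcome, not an error).  Assignments are scored against gold label
sets with per-label binary confusion counts and precision / recall / F.

Aggregation: within each group (e.g. disease) precision and recall are
micro-averaged over labels.  Two F variants are reported, because they answer
different questions and published per-group figures are not always explicit
about which is used: ``f_micro`` (harmonic mean of the micro-averaged P and R)
and ``f_macro_topics`` (arithmetic mean of per-label F within the group).  The
overall summary row is the arithmetic mean of per-group values.

Metrics with a zero denominator are undefined; they are returned as ``None``
and excluded from averages (with a warning), never silently treated as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabelAssignment", "ConfusionCounts", "EvaluationReport",
    "threshold_labels", "assign_labels", "confusion",
    "precision", "recall", "f_score", "evaluate", "mean_of_defined",
]


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def threshold_labels(
    theta_row: Sequence[float],
    labels: Optional[Sequence[str]] = None,
) -> set:
    """Labels whose probability strictly exceeds 1/L.

    ``labels`` maps positions to label ids; without it, positional indices are
    returned.  A uniform row (every entry exactly 1/L) yields the empty set.
    """
    row = np.asarray(theta_row, dtype=float)
    L = row.shape[0]
    hits = np.flatnonzero(row > 1.0 / L)
    if labels is None:
        return set(int(i) for i in hits)
    if len(labels) != L:
        raise ValueError("labels must parallel theta_row")
    return {labels[int(i)] for i in hits}


@dataclass
class LabelAssignment:
    doc_id: str
    assigned: set
    theta_row: np.ndarray


def assign_labels(
    theta: np.ndarray,
    doc_ids: Sequence[str],
    labels: Sequence[str],
) -> list[LabelAssignment]:
    """Apply the 1/L rule to every row of a document-topic matrix."""
    if theta.shape[0] != len(doc_ids):
        raise ValueError("doc_ids must parallel theta rows")
    return [
        LabelAssignment(doc_ids[d], threshold_labels(theta[d], labels), theta[d])
        for d in range(theta.shape[0])
    ]


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    assignments: Mapping[str, set],
    gold: Mapping[str, set],
    labels: Sequence[str],
) -> tuple[dict[str, ConfusionCounts], ConfusionCounts]:
    """Per-label binary confusion counts plus their aggregate.

    Both mappings must cover the same documents; a document present in only
    one of them is an error (silent asymmetry would bias every metric).
    """
    if set(assignments) != set(gold):
        missing = set(assignments) ^ set(gold)
        raise ValueError(f"assignment/gold doc sets differ, e.g. {sorted(missing)[:5]}")
    per_label = {lab: ConfusionCounts() for lab in labels}
    for doc_id, assigned in assignments.items():
        truth = gold[doc_id]
        for lab in labels:
            a, g = lab in assigned, lab in truth
            c = per_label[lab]
            if a and g:
                c.tp += 1
            elif a and not g:
                c.fp += 1
            elif not a and g:
                c.fn += 1
            else:
                c.tn += 1
    aggregate = ConfusionCounts()
    for c in per_label.values():
        aggregate = aggregate + c
    return per_label, aggregate


def precision(counts: ConfusionCounts) -> Optional[float]:
    """tp / (tp + fp); ``None`` when nothing was retrieved."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else None


def recall(counts: ConfusionCounts) -> Optional[float]:
    """tp / (tp + fn); ``None`` when nothing was relevant."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else None


def f_score(p: Optional[float], r: Optional[float]) -> Optional[float]:
    """Harmonic mean 2PR/(P+R); 0 when P+R = 0; ``None`` if either is undefined."""
    if p is None or r is None:
        return None
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def mean_of_defined(values: Sequence[Optional[float]],
                    what: str = "metric") -> Optional[float]:
    """Arithmetic mean excluding undefined entries (logged, not zero-filled)."""
    defined = [v for v in values if v is not None]
    n_undef = len(values) - len(defined)
    if n_undef:
        warnings.warn(f"{n_undef} undefined {what} value(s) excluded from average")
    return sum(defined) / len(defined) if defined else None


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-group classification scores plus their arithmetic-mean summary."""

    per_group: pd.DataFrame           # group, n_docs, precision, recall, f_micro, f_macro_topics
    macro: dict[str, Optional[float]]
    labels: list[str] = field(default_factory=list)

    def to_csv(self, path) -> None:
        df = self.per_group.copy()
        avg = {"group": "Average", "n_docs": int(df["n_docs"].sum()),
               **{k: v for k, v in self.macro.items()}}
        pd.concat([df, pd.DataFrame([avg])], ignore_index=True).to_csv(
            path, index=False)


def evaluate(
    assignments: Mapping[str, set],
    gold: Mapping[str, set],
    groups: Mapping[str, str],
    labels: Sequence[str],
) -> EvaluationReport:
    """Score assignments against gold labels, grouped by ``groups`` (doc id ->
    group tag, e.g. disease).

    Groups with no gold labels at all are excluded with a warning.  The macro
    row is the arithmetic mean of per-group values.
    """
    group_docs: dict[str, list[str]] = {}
    for doc_id in assignments:
        g = groups.get(doc_id)
        if g is not None:
            group_docs.setdefault(g, []).append(doc_id)
    if not group_docs:
        raise ValueError("no document maps to any group")

    rows = []
    for g, docs in group_docs.items():
        if not any(gold[d] for d in docs):
            warnings.warn(f"group {g!r} has no gold labels; excluded")
            continue
        per_label, agg = confusion(
            {d: assignments[d] for d in docs},
            {d: gold[d] for d in docs}, labels)
        p, r = precision(agg), recall(agg)
        label_fs = []
        for lab in labels:
            c = per_label[lab]
            if c.tp + c.fn == 0 and c.tp + c.fp == 0:
                continue     # label absent from this group entirely
            label_fs.append(f_score(precision(c), recall(c)))
        rows.append({
            "group": g, "n_docs": len(docs),
            "precision": p, "recall": r,
            "f_micro": f_score(p, r),
            "f_macro_topics": mean_of_defined(label_fs, "per-label F"),
        })
    df = pd.DataFrame(rows)
    macro = {
        col: mean_of_defined(list(df[col]), col)
        for col in ("precision", "recall", "f_micro", "f_macro_topics")
    }
    return EvaluationReport(df, macro, list(labels))
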