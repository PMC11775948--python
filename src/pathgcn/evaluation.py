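"""Evaluation metrics for single-class and mixed-membership prediction.

Single-class models are scored by top-n accuracy (n = 1, 2, 3): the
prediction is counted correct if the true class is among the n
highest-probability classes.  Multi-label predictions are scored bit-wise
against 11-bit association strings: cumulative TP/TN/FP/FN counts drive
accuracy = 100 · (correct bits) / (11 · N), micro precision and recall,
per-compound Hamming loss and exact match, and per-class
accuracy/precision/recall/MCC.  Paired classifiers are compared with the
exact (binomial) McNemar test on their discordant outcomes.

Undefined ratios (zero denominators) are surfaced as ``None`` rather than
silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .chem_io import N_CLASSES, parse_bitstring


@dataclass(frozen=True)
class ConfusionCounts:
    """Cumulative bit-wise confusion counts over membership vectors."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def _as_bits(x) -> np.ndarray:
    if isinstance(x, str):
        return parse_bitstring(x)
    arr = np.asarray(x, dtype=np.int64)
    if arr.shape != (N_CLASSES,) or not np.isin(arr, (0, 1)).all():
        raise ValueError(f"expected an {N_CLASSES}-bit membership vector, got {x!r}")
    return arr


def bitstring_confusion(true_bits, pred_bits) -> ConfusionCounts:
    """Element-wise TP/TN/FP/FN between two 11-bit association strings."""
    t = _as_bits(true_bits)
    p = _as_bits(pred_bits)
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def confusion_from_matrices(true_matrix, pred_matrix) -> ConfusionCounts:
    """Cumulative confusion counts over an (M, 11) prediction matrix."""
    t = np.asarray(true_matrix, dtype=np.int64)
    p = np.asarray(pred_matrix, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 2 or t.shape[1] != N_CLASSES:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def topn_accuracy(probs: np.ndarray, labels: np.ndarray, n: int) -> float:
    """Percent of rows whose true class is among the n top-ranked classes.

    Ties in probability are broken toward the lower class index, so rank
    order is deterministic.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if not 1 <= n <= N_CLASSES:
        raise ValueError(f"n must be in 1..{N_CLASSES}, got {n}")
    if probs.ndim != 2 or probs.shape[1] != N_CLASSES:
        raise ValueError(f"probs must be (M, {N_CLASSES}), got {probs.shape}")
    # stable argsort on descending probability keeps lower indices first
    order = np.argsort(-probs, axis=1, kind="stable")
    hits = (order[:, :n] == labels[:, None]).any(axis=1)
    return 100.0 * float(hits.mean())


def multilabel_accuracy(true_matrix, pred_matrix) -> float:
    """Percent of correctly predicted compound-class associations."""
    c = confusion_from_matrices(true_matrix, pred_matrix)
    return 100.0 * (c.tp + c.tn) / c.total


def precision_recall(counts: ConfusionCounts) -> tuple[float | None, float | None]:
    """Micro precision TP/(TP+FP) and recall TP/(TP+FN).

    A zero denominator yields ``None`` (undefined), never a silent 0.
    """
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    return precision, recall


def hamming_exact(true_matrix, pred_matrix) -> tuple[float, float]:
    """(Hamming loss, exact-match score) over membership matrices.

    Hamming loss is the mean fraction of mismatched bits per compound;
    exact match is the fraction of compounds with all 11 bits correct.
    """
    t = np.asarray(true_matrix, dtype=np.int64)
    p = np.asarray(pred_matrix, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 2 or t.shape[1] != N_CLASSES:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    mismatch = (t != p)
    hamming = float(mismatch.mean(axis=1).mean())
    exact = float((~mismatch.any(axis=1)).mean())
    return hamming, exact


def _binary_metrics(t: np.ndarray, p: np.ndarray) -> dict:
    tp = int(np.sum((t == 1) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    total = tp + tn + fp + fn
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else None
    return {
        "accuracy": (tp + tn) / total,
        "precision": precision,
        "recall": recall,
        "mcc": mcc,
    }


def classwise_metrics(true_matrix, pred_matrix) -> list[dict]:
    """Per-class binary accuracy/precision/recall/MCC over column c.

    Degenerate denominators (a class never predicted, or never present)
    surface as ``None`` in the affected metric.
    """
    t = np.asarray(true_matrix, dtype=np.int64)
    p = np.asarray(pred_matrix, dtype=np.int64)
    if t.shape != p.shape or t.ndim != 2 or t.shape[1] != N_CLASSES:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    return [_binary_metrics(t[:, c], p[:, c]) for c in range(N_CLASSES)]


def mcnemar(
    correct_a: np.ndarray, correct_b: np.ndarray, exact: bool = True
) -> float:
    """Two-sided McNemar p-value for paired classifier comparisons.

    ``correct_a`` / ``correct_b`` are 0/1 indicators of correctness over
    the same test items.  With ``exact=True`` (default, appropriate for
    the few-hundred-item test sets here) the p-value is the exact
    two-sided binomial tail on the discordant pairs; ``exact=False`` uses
    the continuity-corrected chi-squared approximation.  Zero discordant
    pairs yield p = 1.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("correctness indicators must be 1-D and aligned")
    n_only_a = int(np.sum(a & ~b))
    n_only_b = int(np.sum(~a & b))
    n_disc = n_only_a + n_only_b
    if n_disc == 0:
        return 1.0
    if exact:
        p = 2.0 * float(binom.cdf(min(n_only_a, n_only_b), n_disc, 0.5))
        # both tails overlap at the midpoint when b == c
        return min(1.0, p)
    from scipy.stats import chi2

    stat = (abs(n_only_a - n_only_b) - 1) ** 2 / n_disc
    return float(chi2.sf(stat, df=1))


def evaluation_report(
    *,
    top_n: dict[int, float] | None = None,
    true_matrix=None,
    pred_matrix=None,
    mcnemar_pairs: dict[str, float] | None = None,
) -> dict:
    """Assemble a versioned evaluation report dictionary.

    Includes whichever of the single-class (top-n) and multi-label blocks
    the caller supplies; the multi-label block covers cumulative confusion
    counts, micro precision/recall, Hamming loss, exact match and
    per-class metrics.
    """
    report: dict = {"schema_version": 1}
    if top_n is not None:
        report["top_n"] = {str(k): v for k, v in top_n.items()}
    if true_matrix is not None and pred_matrix is not None:
        counts = confusion_from_matrices(true_matrix, pred_matrix)
        precision, recall = precision_recall(counts)
        hamming, exact = hamming_exact(true_matrix, pred_matrix)
        report["multilabel"] = {
            "confusion": {
                "tp": counts.tp,
                "tn": counts.tn,
                "fp": counts.fp,
                "fn": counts.fn,
            },
            "accuracy_percent": multilabel_accuracy(true_matrix, pred_matrix),
            "precision": precision,
            "recall": recall,
            "hamming_loss": hamming,
            "exact_match": exact,
            "per_class": classwise_metrics(true_matrix, pred_matrix),
        }
    if mcnemar_pairs is not None:
        report["mcnemar"] = mcnemar_pairs
    return report
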