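"""Exact EC prediction metrics: hierarchical multi-label precision/recall/F1.

Model performance is evaluated at increasing levels of specificity (EC
levels 1-4).  At level ``k`` every true and predicted label is truncated to
its first ``k`` levels and de-duplicated per protein, then per-class binary
confusion counts are accumulated one-vs-rest over the union label space.

Conventions (documented in every report):

* A protein whose every true label is shallower than the evaluated level is
  excluded from that level (a partial annotation carries no ground truth
  there; completion is a separate task).  Predicted labels shallower than
  the level are likewise dropped.
* 0/0 metric cells are 0 (conservative standard convention).
* ``weighted`` averages weight by true support (tp + fn), so
  prediction-only classes cannot inflate scores; ``macro`` averages
  uniformly over classes with support > 0; ``micro`` derives from summed
  tp/fp/fn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np

from .ec_core import ECLabel
from .io_formats import AnnotationTable

__all__ = [
    "ClassStats",
    "LevelMetrics",
    "MetricsReport",
    "BatchedMetrics",
    "evaluate_level",
    "evaluate_all_levels",
    "evaluate_batched",
    "evaluate_by_group",
    "per_class_table",
]

AGGREGATE_KEYS = (
    "micro_precision", "micro_recall", "micro_f1",
    "macro_precision", "macro_recall", "macro_f1",
    "weighted_precision", "weighted_recall", "weighted_f1",
)


def _prf(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


@dataclass(frozen=True)
class ClassStats:
    support: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float

    def to_dict(self) -> dict:
        return {
            "support": self.support, "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


@dataclass
class LevelMetrics:
    """Per-class and aggregate metrics at one EC level."""

    level: int
    n_proteins: int
    per_class: Dict[ECLabel, ClassStats]
    aggregates: Dict[str, float]

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "n_proteins": self.n_proteins,
            "aggregates": dict(self.aggregates),
            "per_class": [
                {"ec": str(ec), **self.per_class[ec].to_dict()}
                for ec in sorted(self.per_class, key=str)
            ],
        }


@dataclass
class MetricsReport:
    """Levels 1-4 metrics for one model, plus optional batch variance."""

    model_name: str
    levels: List[LevelMetrics]
    batch_stats: Optional[Dict[int, "BatchedMetrics"]] = None
    notes: Dict[str, str] = field(default_factory=lambda: {
        "zero_division": "0/0 metric cells are reported as 0",
        "partial_labels": "true/predicted labels shallower than the level are excluded at that level",
    })

    def to_dict(self) -> dict:
        doc = {
            "model": self.model_name,
            "notes": dict(self.notes),
            "levels": [lm.to_dict() for lm in self.levels],
        }
        if self.batch_stats is not None:
            doc["batch_stats"] = {
                str(level): bs.to_dict() for level, bs in self.batch_stats.items()
            }
        return doc


@dataclass
class BatchedMetrics:
    """Mean and standard deviation of each aggregate over disjoint batches."""

    level: int
    n_batches: int
    batch_sizes: List[int]
    mean: Dict[str, float]
    sd: Dict[str, float]

    def to_dict(self) -> dict:
        return {
            "level": self.level, "n_batches": self.n_batches,
            "batch_sizes": list(self.batch_sizes),
            "mean": dict(self.mean), "sd": dict(self.sd),
        }


# ---------------------------------------------------------------------------

def _truncate_sets(
    truth: AnnotationTable,
    predicted: Mapping[str, Iterable[ECLabel]],
    level: int,
) -> Dict[str, Tuple[Set[ECLabel], Set[ECLabel]]]:
    """Truncated, de-duplicated (true, predicted) label sets per eligible protein."""
    out = {}
    for pid, labels in truth.entries.items():
        true_trunc = {t.truncate(level) for t in labels if t.depth >= level}
        if not true_trunc:
            continue  # no ground truth at this depth
        pred_trunc = {
            p.truncate(level) for p in predicted.get(pid, ()) if p.depth >= level
        }
        out[pid] = (true_trunc, pred_trunc)
    return out


def evaluate_level(
    truth: AnnotationTable,
    predicted: Mapping[str, Set[ECLabel]],
    level: int,
) -> LevelMetrics:
    """One-vs-rest multi-label metrics at one EC level.

    Parameters
    ----------
    truth
        Ground-truth annotations (may contain partial labels).
    predicted
        Mapping protein -> set of predicted labels (thresholds already
        applied).  Proteins absent from the mapping predict nothing.
    level
        EC level 1-4.
    """
    if not 1 <= level <= 4:
        raise ValueError(f"level must be in 1..4, got {level}")
    if len(truth) == 0:
        raise ValueError("empty truth table")

    pairs = _truncate_sets(truth, predicted, level)
    counts: Dict[ECLabel, List[int]] = {}  # class -> [tp, fp, fn]
    for true_set, pred_set in pairs.values():
        for ec in true_set & pred_set:
            counts.setdefault(ec, [0, 0, 0])[0] += 1
        for ec in pred_set - true_set:
            counts.setdefault(ec, [0, 0, 0])[1] += 1
        for ec in true_set - pred_set:
            counts.setdefault(ec, [0, 0, 0])[2] += 1

    per_class: Dict[ECLabel, ClassStats] = {}
    for ec, (tp, fp, fn) in counts.items():
        p, r, f1 = _prf(tp, fp, fn)
        per_class[ec] = ClassStats(tp + fn, tp, fp, fn, p, r, f1)

    agg: Dict[str, float] = {}
    tp_sum = sum(s.tp for s in per_class.values())
    fp_sum = sum(s.fp for s in per_class.values())
    fn_sum = sum(s.fn for s in per_class.values())
    agg["micro_precision"], agg["micro_recall"], agg["micro_f1"] = _prf(
        tp_sum, fp_sum, fn_sum
    )
    supported = [s for s in per_class.values() if s.support > 0]
    total_support = sum(s.support for s in supported)
    for name in ("precision", "recall", "f1"):
        vals = np.array([getattr(s, name) for s in supported])
        weights = np.array([s.support for s in supported], dtype=float)
        agg[f"macro_{name}"] = float(vals.mean()) if supported else 0.0
        agg[f"weighted_{name}"] = (
            float((vals * weights).sum() / total_support) if total_support else 0.0
        )
    return LevelMetrics(level=level, n_proteins=len(pairs), per_class=per_class,
                        aggregates=agg)


def evaluate_all_levels(
    truth: AnnotationTable,
    predicted: Mapping[str, Set[ECLabel]],
    model_name: str = "model",
) -> MetricsReport:
    """Convenience wrapper: levels 1-4 in one report."""
    return MetricsReport(
        model_name=model_name,
        levels=[evaluate_level(truth, predicted, lv) for lv in (1, 2, 3, 4)],
    )


def evaluate_batched(
    truth: AnnotationTable,
    predicted: Mapping[str, Set[ECLabel]],
    level: int,
    n_batches: int = 5,
    seed: int = 17,
) -> BatchedMetrics:
    """Aggregate mean +/- sd over equal-sized, non-overlapping batches.

    Proteins eligible at ``level`` are shuffled with ``seed`` and split
    into ``n_batches`` disjoint subsets that together cover the test set
    (sizes differ by at most one); :func:`evaluate_level` runs per subset.
    The standard deviation is the sample sd (ddof=1).
    """
    if n_batches < 2:
        raise ValueError("n_batches must be >= 2")
    eligible = sorted(
        pid for pid, labels in truth.entries.items()
        if any(t.depth >= level for t in labels)
    )
    if len(eligible) < n_batches:
        raise ValueError(
            f"fewer eligible proteins ({len(eligible)}) than batches ({n_batches})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(eligible))
    batches = np.array_split(np.asarray(eligible, dtype=object)[order], n_batches)

    rows = []
    for batch in batches:
        sub_truth = truth.restrict(batch.tolist())
        lm = evaluate_level(sub_truth, predicted, level)
        rows.append([lm.aggregates[k] for k in AGGREGATE_KEYS])
    arr = np.array(rows)
    return BatchedMetrics(
        level=level,
        n_batches=n_batches,
        batch_sizes=[len(b) for b in batches],
        mean=dict(zip(AGGREGATE_KEYS, arr.mean(axis=0))),
        sd=dict(zip(AGGREGATE_KEYS, arr.std(axis=0, ddof=1))),
    )


def evaluate_by_group(
    truth: AnnotationTable,
    predicted: Mapping[str, Set[ECLabel]],
    level: int,
    groups: Mapping[str, str],
) -> Dict[str, LevelMetrics]:
    """Per-group metrics (e.g. separate Eukaryotic and Bacterial scores).

    Proteins without a group entry fall into group ``"ungrouped"``.  Every
    grouped protein must appear in the truth table.
    """
    unknown = set(groups) - set(truth.entries)
    if unknown:
        raise ValueError(f"grouped proteins absent from truth: {sorted(unknown)[:5]}")
    by_group: Dict[str, List[str]] = {}
    for pid in truth.entries:
        by_group.setdefault(groups.get(pid, "ungrouped"), []).append(pid)
    return {
        g: evaluate_level(truth.restrict(pids), predicted, level)
        for g, pids in sorted(by_group.items())
    }


def per_class_table(
    truth: AnnotationTable,
    predicted: Mapping[str, Set[ECLabel]],
) -> Dict[ECLabel, dict]:
    """Per-EC-node F1/support across all four levels (sunburst input).

    The node set is the union of truncations of all true and predicted
    labels; a node at depth ``k`` carries the level-``k`` per-class stats.
    """
    table: Dict[ECLabel, dict] = {}
    for level in (1, 2, 3, 4):
        lm = evaluate_level(truth, predicted, level)
        for ec, stats in lm.per_class.items():
            table[ec] = stats.to_dict()
    return table
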