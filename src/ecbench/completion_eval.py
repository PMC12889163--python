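"""EC-number completion scored by inter-model agreement.

Many enzymes are only partially annotated (``1.1.-.-``).  Because the true
completed EC numbers are unknown, completion is scored by consensus: an
incomplete entry counts as *agreed* when strictly more than half of the
compared models return the same EC number as their top prediction for that
protein.  The *agreement rate* is the fraction of incomplete entries with
such a majority; each model's *agreement count* is the number of entries
where its top prediction matched the majority label.

On proteins with fully known EC numbers, agreement count correlates with
the model's F1 score, which justifies consensus as a confidence measure
where truth is unavailable (:func:`validate_agreement`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from .ec_core import ECLabel
from .exact_eval import evaluate_level
from .io_formats import AnnotationTable, PredictionTable

__all__ = [
    "AgreementResult",
    "find_incomplete",
    "top_prediction",
    "agreement",
    "validate_agreement",
]

Entry = Tuple[str, ECLabel]  # (protein, partial label)


@dataclass
class AgreementResult:
    """Consensus outcome over a set of incomplete-EC entries."""

    entries: List[Entry]
    #: entry -> (majority label or None, {model -> top label or None})
    per_entry: Dict[Entry, Tuple[Optional[ECLabel], Dict[str, Optional[ECLabel]]]]
    agreement_rate: float
    per_model_agreement_count: Dict[str, int]
    #: fraction of each model's top predictions that extend the partial prefix
    per_model_prefix_consistency: Dict[str, float]
    #: model -> (mean, sd) of agreement counts over seeded entry batches
    batch_stats: Optional[Dict[str, Tuple[float, float]]] = None

    def to_rows(self) -> List[dict]:
        rows = []
        for entry in self.entries:
            majority, tops = self.per_entry[entry]
            row = {
                "protein": entry[0],
                "partial_ec": str(entry[1]),
                "majority_ec": str(majority) if majority is not None else "NONE",
            }
            for model, top in sorted(tops.items()):
                row[f"top:{model}"] = str(top) if top is not None else "NONE"
            rows.append(row)
        return rows


def find_incomplete(truth: AnnotationTable) -> List[Entry]:
    """All (protein, label) pairs whose label has depth < 4, sorted."""
    out = [
        (pid, ec)
        for pid, labels in truth.entries.items()
        for ec in labels
        if ec.depth < 4
    ]
    out.sort(key=lambda e: (e[0], str(e[1])))
    return out


def top_prediction(preds: PredictionTable, protein: str) -> Optional[ECLabel]:
    """The model's highest-scoring label for ``protein``; ties break to the
    smallest canonical EC string; ``None`` when the protein is absent."""
    return preds.top_label(protein)


def _tally(
    models: Sequence[PredictionTable],
    entry: Entry,
    denominator: str,
) -> Tuple[Optional[ECLabel], Dict[str, Optional[ECLabel]]]:
    pid = entry[0]
    tops = {m.model_name: top_prediction(m, pid) for m in models}
    counts: Dict[ECLabel, int] = {}
    for top in tops.values():
        if top is not None:
            counts[top] = counts.get(top, 0) + 1
    n = len(models) if denominator == "all" else sum(
        1 for t in tops.values() if t is not None
    )
    majority = None
    for ec in sorted(counts, key=str):
        if counts[ec] * 2 > n:  # strictly more than half
            majority = ec
            break
    return majority, tops


def agreement(
    models: Sequence[PredictionTable],
    entries: Sequence[Entry],
    denominator: str = "all",
    n_batches: int = 0,
    seed: int = 17,
) -> AgreementResult:
    """Consensus over incomplete entries.

    ``denominator="all"`` (default) counts abstaining models in the
    majority denominator, reading "more than half of the models" literally;
    ``"voters"`` restricts the denominator to models that predicted.
    With ``n_batches >= 2`` the entries are shuffled with ``seed``, split
    into equal non-overlapping batches, and per-model agreement counts are
    summarized as mean +/- sample sd for error-bar plots.
    """
    if len(models) < 3:
        raise ValueError("agreement needs at least 3 models")
    if not entries:
        raise ValueError("no incomplete entries to evaluate")
    if denominator not in ("all", "voters"):
        raise ValueError(f"unknown denominator {denominator!r}")

    model_names = [m.model_name for m in models]
    per_entry = {}
    counts = {name: 0 for name in model_names}
    prefix_hits = {name: 0 for name in model_names}
    prefix_total = {name: 0 for name in model_names}
    n_agreed = 0
    for entry in entries:
        majority, tops = _tally(models, entry, denominator)
        per_entry[entry] = (majority, tops)
        if majority is not None:
            n_agreed += 1
            for name, top in tops.items():
                if top == majority:
                    counts[name] += 1
        for name, top in tops.items():
            if top is not None:
                prefix_total[name] += 1
                if top.completes(entry[1]):
                    prefix_hits[name] += 1

    batch_stats = None
    if n_batches >= 2:
        if len(entries) < n_batches:
            raise ValueError("fewer entries than batches")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(entries))
        splits = np.array_split(order, n_batches)
        per_model_rows = {name: [] for name in model_names}
        for split in splits:
            batch_counts = {name: 0 for name in model_names}
            for idx in split:
                majority, tops = per_entry[entries[idx]]
                if majority is None:
                    continue
                for name, top in tops.items():
                    if top == majority:
                        batch_counts[name] += 1
            for name in model_names:
                per_model_rows[name].append(batch_counts[name])
        batch_stats = {
            name: (float(np.mean(v)), float(np.std(v, ddof=1)))
            for name, v in per_model_rows.items()
        }

    return AgreementResult(
        entries=list(entries),
        per_entry=per_entry,
        agreement_rate=n_agreed / len(entries),
        per_model_agreement_count=counts,
        per_model_prefix_consistency={
            name: (prefix_hits[name] / prefix_total[name]) if prefix_total[name] else 0.0
            for name in model_names
        },
        batch_stats=batch_stats,
    )


def validate_agreement(
    models: Sequence[PredictionTable],
    complete_truth: AnnotationTable,
    level: int = 4,
    denominator: str = "all",
) -> dict:
    """Correlate per-model agreement count with F1 on fully annotated proteins.

    The agreement machinery runs over proteins whose every label is
    complete (treating each full label as the entry); each model's
    weighted F1 at ``level`` comes from the exact-prediction task using
    the model's top label per protein.  Returns per-model
    ``(agreement_count, f1)`` pairs and the Pearson correlation with its
    two-sided p-value (``NA`` when either variable has zero variance).
    """
    complete = {
        pid: labels
        for pid, labels in complete_truth.entries.items()
        if all(ec.depth == 4 for ec in labels)
    }
    if len(complete) < 3:
        raise ValueError("need at least 3 completely annotated proteins")
    if len(models) < 3:
        raise ValueError("need at least 3 models")
    truth = AnnotationTable(complete)
    entries = [
        (pid, ec) for pid, labels in sorted(complete.items()) for ec in sorted(labels, key=str)
    ]
    result = agreement(models, entries, denominator=denominator)

    pairs = {}
    counts, f1s = [], []
    for m in models:
        predicted = {
            pid: {m.top_label(pid)} for pid in complete if m.top_label(pid) is not None
        }
        f1 = evaluate_level(truth, predicted, level).aggregates["weighted_f1"]
        c = result.per_model_agreement_count[m.model_name]
        pairs[m.model_name] = (c, f1)
        counts.append(c)
        f1s.append(f1)

    counts_a, f1_a = np.array(counts, dtype=float), np.array(f1s, dtype=float)
    if counts_a.std() == 0 or f1_a.std() == 0:
        r, p = None, None  # zero variance: correlation undefined
    else:
        r, p = (float(v) for v in sstats.pearsonr(counts_a, f1_a))
    return {"per_model": pairs, "pearson_r": r, "p_value": p}
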