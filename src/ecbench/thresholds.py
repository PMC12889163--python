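"""Convert scored predictions into label sets.

Two strategies mirror the two model flavours the benchmark evaluates:

* **regular** — a fixed rule: always emit the top-scoring label (argmax),
  plus every additional label whose score reaches ``t_extra``, so
  multi-function enzymes get multiple EC numbers when confidence is high.
* **learnt** — per-class thresholds fitted on a validation split to
  maximize each class's binary F1, which helps precision and recall
  especially for rare classes.

Threshold comparison is inclusive (``>=``) throughout, so a learnt
threshold equal to a positive's score keeps that positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Set, Tuple, Union

from .ec_core import ECLabel, parse_ec
from .io_formats import AnnotationTable, PredictionTable

__all__ = ["NEVER", "ThresholdMap", "apply_regular", "learn_thresholds",
           "apply_thresholds"]


class _Never:
    """Sentinel: the class is never emitted regardless of score."""

    def __repr__(self):
        return "NEVER"


NEVER = _Never()

Threshold = Union[float, _Never]


@dataclass
class ThresholdMap:
    """Per-class decision thresholds with a default for unseen classes."""

    default_threshold: float = 0.5
    per_class: Dict[ECLabel, Threshold] = field(default_factory=dict)

    def threshold_for(self, ec: ECLabel) -> Threshold:
        return self.per_class.get(ec, self.default_threshold)

    # -- TSV persistence (ec, threshold) with a "NEVER" sentinel ------------
    def write_tsv(self, path) -> None:
        with Path(path).open("w") as fh:
            fh.write("ec_number\tthreshold\n")
            fh.write(f"__default__\t{self.default_threshold:.17g}\n")
            for ec in sorted(self.per_class, key=str):
                t = self.per_class[ec]
                fh.write(f"{ec}\t{'NEVER' if isinstance(t, _Never) else format(t, '.17g')}\n")

    @classmethod
    def read_tsv(cls, path) -> "ThresholdMap":
        default = 0.5
        per_class: Dict[ECLabel, Threshold] = {}
        with Path(path).open() as fh:
            header = fh.readline()
            if not header.startswith("ec_number\tthreshold"):
                raise ValueError(f"{path}: unexpected header {header!r}")
            for line in fh:
                if not line.strip():
                    continue
                ec_text, t_text = line.rstrip("\n").split("\t")
                if ec_text == "__default__":
                    default = float(t_text)
                elif t_text == "NEVER":
                    per_class[parse_ec(ec_text)] = NEVER
                else:
                    per_class[parse_ec(ec_text)] = float(t_text)
        return cls(default_threshold=default, per_class=per_class)


def apply_regular(
    preds: PredictionTable, t_extra: float = 0.5
) -> Dict[str, Set[ECLabel]]:
    """Fixed rule: argmax label always, extras at score >= ``t_extra``.

    Argmax ties break to the lexicographically smallest canonical EC string.
    """
    if not 0.0 <= t_extra <= 1.0:
        raise ValueError(f"t_extra must be in [0, 1], got {t_extra}")
    out: Dict[str, Set[ECLabel]] = {}
    for pid, pairs in preds.entries.items():
        if not pairs:
            continue
        top = min(pairs, key=lambda p: (-p[1], str(p[0])))[0]
        labels = {top} | {ec for ec, s in pairs if s >= t_extra}
        out[pid] = labels
    return out


def _binary_f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def learn_thresholds(
    validation_truth: AnnotationTable,
    validation_preds: PredictionTable,
    default_threshold: float = 0.5,
) -> ThresholdMap:
    """Fit per-class F1-optimal thresholds on a validation split.

    For each class with at least one validation positive, the candidate set
    is the class's unique observed scores; the candidate maximizing the
    class's binary F1 wins, with ties going to the smallest candidate
    (favours recall).  Classes never positive in validation are marked
    :data:`NEVER`.

    A protein counts as class-positive when the class is in its truth set;
    it counts as predicted-positive at threshold ``t`` when the model
    scored the class at ``>= t`` for that protein (no score = negative).
    """
    if len(validation_truth) == 0:
        raise ValueError("empty validation set")

    # class -> list of (score, is_positive) over validation proteins
    observations: Dict[ECLabel, List[Tuple[float, bool]]] = {}
    positives: Dict[ECLabel, int] = {}
    for pid, labels in validation_truth.entries.items():
        scored = validation_preds.scores_for(pid)
        for ec in labels:
            positives[ec] = positives.get(ec, 0) + 1
        for ec, score in scored.items():
            observations.setdefault(ec, []).append((score, ec in labels))

    per_class: Dict[ECLabel, Threshold] = {}
    for ec, n_pos in positives.items():
        obs = observations.get(ec, [])
        best_t: Threshold = NEVER
        best_f1 = -1.0
        for cand in sorted({s for s, _ in obs}):
            tp = sum(1 for s, is_pos in obs if is_pos and s >= cand)
            fp = sum(1 for s, is_pos in obs if not is_pos and s >= cand)
            fn = n_pos - tp
            f1 = _binary_f1(tp, fp, fn)
            if f1 > best_f1:  # strict: ties keep the smallest candidate
                best_f1, best_t = f1, cand
        # best_t stays NEVER when positives exist but the model never
        # scored the class: nothing to calibrate, suppress it
        per_class[ec] = best_t
    # classes scored by the model but never positive in validation
    for ec in observations:
        if ec not in positives:
            per_class[ec] = NEVER
    return ThresholdMap(default_threshold=default_threshold, per_class=per_class)


def apply_thresholds(
    preds: PredictionTable, tm: ThresholdMap
) -> Dict[str, Set[ECLabel]]:
    """Emit each label iff its score >= its class threshold.

    Unseen classes use the default threshold; :data:`NEVER` suppresses the
    class outright.  A protein whose labels are all suppressed ends with
    the empty set removed (it counts as "no prediction" for coverage).
    """
    out: Dict[str, Set[ECLabel]] = {}
    for pid, pairs in preds.entries.items():
        labels = set()
        for ec, score in pairs:
            t = tm.threshold_for(ec)
            if isinstance(t, _Never):
                continue
            if score >= t:
                labels.add(ec)
        if labels:
            out[pid] = labels
    return out
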