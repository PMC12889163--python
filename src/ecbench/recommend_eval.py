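"""Partial/additional EC recommendation scored by reaction similarity.

When a model proposes an EC number that is not exactly right (or only
partially specified), the proposal can still be chemically close: EC
numbers denote reactions, so prediction quality is scored as the Tanimoto
similarity between fingerprints of the reactions catalyzed by the
predicted and true EC numbers (reaction records in the style of the
ECReact collection).

Because reaction tables are incomplete, an EC absent from the table is
scored through seeded surrogate sampling: table ECs sharing its first
three defined levels stand in for it (averaging their similarities to the
other EC), relaxing to two then one shared levels if no three-level
sibling exists.  Model-level summaries follow three quantities:

* ``coverage``   = 100 x (#proteins with >= 1 prediction) / (#proteins),
* ``average``    = mean over predicted proteins of the best predicted-vs-true
  pair similarity,
* ``weighted``   = average x coverage / 100,

so models that predict for more proteins are not penalized unfairly.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .ec_core import ECLabel, parse_ec
from .fingerprints import FingerprintBackend, TokenHashFingerprinter
from .io_formats import AnnotationTable, FormatError, _iter_tsv

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionRecord",
    "ReactionTable",
    "read_reaction_table",
    "write_reaction_table",
    "SimilarityReport",
    "reaction_similarity",
    "best_pair_similarity",
    "similarity_report",
    "select_unseen",
    "additional_predictions",
]


@dataclass(frozen=True)
class ReactionRecord:
    reaction: str
    fingerprint: object


@dataclass
class ReactionTable:
    """Complete EC label -> reaction records with cached fingerprints."""

    backend: FingerprintBackend
    entries: Dict[ECLabel, List[ReactionRecord]] = field(default_factory=dict)

    def add(self, ec: ECLabel, reaction: str) -> None:
        if not ec.is_complete:
            raise ValueError(f"reaction table keys must be complete ECs, got {ec}")
        self.entries.setdefault(ec, []).append(
            ReactionRecord(reaction, self.backend.fingerprint(reaction))
        )

    def __contains__(self, ec: ECLabel) -> bool:
        return ec in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def siblings(self, ec: ECLabel, level: int) -> List[ECLabel]:
        """Table ECs sharing the first ``level`` tokens with ``ec`` (excluding
        ``ec`` itself), sorted for determinism."""
        prefix = ec.tokens[:level]
        return sorted(
            (k for k in self.entries if k.tokens[:level] == prefix and k != ec),
            key=str,
        )


def read_reaction_table(path, backend: Optional[FingerprintBackend] = None,
                        lenient: bool = False) -> ReactionTable:
    """Read a TSV with columns ``ec_number``, ``reaction``
    (``reactants>>products``, molecules ``.``-separated)."""
    table = ReactionTable(backend=backend or TokenHashFingerprinter())
    for line_no, (ec_text, reaction) in _iter_tsv(path, ["ec_number", "reaction"]):
        try:
            table.add(parse_ec(ec_text), reaction.strip())
        except ValueError as exc:
            if lenient:
                logger.warning("skipping %s:%d: %s", path, line_no, exc)
                continue
            raise FormatError(path, line_no, str(exc)) from exc
    if not table.entries:
        raise FormatError(path, None, "empty reaction table")
    return table


def write_reaction_table(table: ReactionTable, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("ec_number\treaction\n")
        for ec in sorted(table.entries, key=str):
            for rec in table.entries[ec]:
                fh.write(f"{ec}\t{rec.reaction}\n")


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

def _direct_similarity(a: ECLabel, b: ECLabel, table: ReactionTable) -> float:
    """Max pairwise fingerprint Tanimoto over the two ECs' reaction records.

    An EC matches if any reaction it catalyzes matches, hence max over
    record pairs.
    """
    best = 0.0
    for ra in table.entries[a]:
        for rb in table.entries[b]:
            sim = table.backend.tanimoto(ra.fingerprint, rb.fingerprint)
            if sim > best:
                best = sim
    return best


def _surrogates(
    ec: ECLabel, table: ReactionTable, rng_seed: int, max_samples: int
) -> List[ECLabel]:
    """Seeded surrogate sample for an EC absent from the table.

    Starts from siblings sharing the first three defined levels and relaxes
    one level at a time; sampling is without replacement, deterministic
    given ``rng_seed`` and the EC (each EC derives its own stream so the
    sample does not depend on evaluation order).
    """
    start = min(3, ec.depth) if ec.depth else 1
    for level in range(start, 0, -1):
        sibs = table.siblings(ec, level)
        if sibs:
            if len(sibs) <= max_samples:
                return sibs
            sub_seed = (rng_seed + zlib.crc32(str(ec).encode())) % (2**31)
            rng = np.random.default_rng(sub_seed)
            picked = rng.choice(len(sibs), size=max_samples, replace=False)
            return [sibs[i] for i in sorted(picked)]
    return []


def reaction_similarity(
    a: ECLabel,
    b: ECLabel,
    table: ReactionTable,
    rng_seed: int = 17,
    max_samples: int = 10,
) -> float:
    """Reaction similarity between two EC numbers, in [0, 1].

    Both ECs in the table: maximum pairwise Tanimoto over their reaction
    records.  An absent (or partial) EC is replaced by up to
    ``max_samples`` seeded sibling surrogates and the similarities are
    averaged.  If no sibling exists at any level the pair scores 0 and a
    warning is logged, keeping report denominators well defined.
    """
    if max_samples < 1:
        raise ValueError("max_samples must be >= 1")
    if len(table) == 0:
        raise ValueError("empty reaction table")
    a_in, b_in = a in table, b in table
    if a_in and b_in:
        return _direct_similarity(a, b, table)
    reps_a = [a] if a_in else _surrogates(a, table, rng_seed, max_samples)
    reps_b = [b] if b_in else _surrogates(b, table, rng_seed, max_samples)
    if not reps_a or not reps_b:
        logger.warning(
            "no reaction-table surrogate at any level for %s; scoring 0",
            a if not reps_a else b,
        )
        return 0.0
    sims = [
        _direct_similarity(ra, rb, table) for ra in reps_a for rb in reps_b
    ]
    return float(np.mean(sims))


def best_pair_similarity(
    predicted: Set[ECLabel],
    true: Set[ECLabel],
    table: ReactionTable,
    rng_seed: int = 17,
    max_samples: int = 10,
) -> float:
    """Max of :func:`reaction_similarity` over all (predicted, true) pairs."""
    if not predicted or not true:
        raise ValueError("best_pair_similarity needs non-empty label sets")
    return max(
        reaction_similarity(p, t, table, rng_seed=rng_seed, max_samples=max_samples)
        for p in sorted(predicted, key=str)
        for t in sorted(true, key=str)
    )


@dataclass
class SimilarityReport:
    """Model-level coverage / average / weighted similarity summary."""

    model: str
    coverage: float  # percentage in [0, 100]
    average_similarity: Optional[float]  # None when no protein predicted
    weighted_similarity: float
    per_protein: Dict[str, float]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "coverage": self.coverage,
            "average_similarity": self.average_similarity,
            "weighted_similarity": self.weighted_similarity,
            "per_protein": {p: s for p, s in sorted(self.per_protein.items())},
        }


def similarity_report(
    preds: Mapping[str, Set[ECLabel]],
    truth: AnnotationTable,
    table: ReactionTable,
    rng_seed: int = 17,
    max_samples: int = 10,
    model: str = "model",
    truncate_predictions: Optional[int] = None,
) -> SimilarityReport:
    """Coverage, average and weighted reaction similarity for one model.

    ``truncate_predictions`` optionally truncates every predicted label to
    that EC level before scoring (the partial-recommendation task can be
    run either on full predictions or on their level-1..3 truncations;
    truncated labels are scored through the surrogate fallback).
    """
    if len(truth) == 0:
        raise ValueError("empty truth table")
    per_protein: Dict[str, float] = {}
    for pid, labels in truth.entries.items():
        plabels = preds.get(pid)
        if not plabels:
            continue
        if truncate_predictions is not None:
            plabels = {p.truncate(truncate_predictions) for p in plabels}
        per_protein[pid] = best_pair_similarity(
            plabels, set(labels), table, rng_seed=rng_seed, max_samples=max_samples
        )
    n_pred = len(per_protein)
    coverage = 100.0 * n_pred / len(truth)
    if n_pred == 0:
        return SimilarityReport(model, 0.0, None, 0.0, {})
    average = float(np.mean(list(per_protein.values())))
    return SimilarityReport(model, coverage, average, average * coverage / 100.0,
                            per_protein)


# ---------------------------------------------------------------------------
# task-specific selections
# ---------------------------------------------------------------------------

def select_unseen(
    test_truth: AnnotationTable, train_truth: AnnotationTable
) -> AnnotationTable:
    """Keep test (protein, label) pairs whose full label occurs in no
    training annotation; proteins left with empty sets are dropped."""
    train_labels = set()
    for labels in train_truth.entries.values():
        train_labels.update(labels)
    kept = {}
    for pid, labels in test_truth.entries.items():
        unseen = frozenset(ec for ec in labels if ec not in train_labels)
        if unseen:
            kept[pid] = unseen
    return AnnotationTable(kept)


def additional_predictions(
    preds: Mapping[str, Set[ECLabel]], truth: AnnotationTable
) -> List[Tuple[str, Set[ECLabel], Set[ECLabel]]]:
    """Proteins where the model matched the annotated function AND proposed
    extra EC numbers (possible corrections or additional functions).

    Returns (protein, matched true labels, extra labels) rows; downstream,
    each extra label is scored against the true set via
    :func:`best_pair_similarity`.
    """
    rows = []
    for pid, labels in sorted(truth.entries.items()):
        plabels = preds.get(pid)
        if not plabels:
            continue
        matched = set(labels) & set(plabels)
        extra = set(plabels) - set(labels)
        if matched and extra:
            rows.append((pid, matched, extra))
    return rows
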