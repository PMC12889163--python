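"""Dataset construction: enzyme filtering, deduplication, and leakage removal.

Benchmark train/test splits must not leak: a model evaluated on a test
protein that is (nearly) identical to a training protein measures memory,
not generalization.  The pipeline here mirrors standard practice:

1. drop non-enzymes (proteins without any EC annotation),
2. de-duplicate identical sequences within a split (annotations merge by
   union),
3. cluster the union of train + test at a percent-identity threshold and
   remove every *training* sequence sharing a cluster with any test
   sequence (the test set is never modified).

Clustering is pluggable: an adapter consumes the two-column TSV cluster
format emitted by standard sequence clusterers (e.g. MMseqs2), and a
built-in greedy clusterer lets everything run with no external binary.
Every step appends to a provenance log with before/after counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Set, Tuple

import edlib

from .io_formats import AnnotationTable, SequenceSet

__all__ = [
    "ProvenanceLog",
    "DatasetBundle",
    "drop_non_enzymes",
    "dedup_sequences",
    "builtin_cluster",
    "read_cluster_tsv",
    "filter_similar",
    "structure_filter",
    "attach_metadata",
    "curate",
    "percent_identity",
]


@dataclass
class ProvenanceLog:
    steps: List[dict] = field(default_factory=list)

    def record(self, step: str, n_before: int, n_after: int, **extra) -> None:
        if self.steps and self.steps[-1]["n_after"] != n_before:
            raise ValueError(
                f"provenance gap: step {step!r} starts from {n_before} but "
                f"previous step ended at {self.steps[-1]['n_after']}"
            )
        self.steps.append({"step": step, "n_before": n_before,
                           "n_after": n_after, **extra})

    def write_json(self, path) -> None:
        with Path(path).open("w") as fh:
            json.dump(self.steps, fh, indent=2)
            fh.write("\n")


@dataclass
class DatasetBundle:
    """A curated train/test split with its provenance."""

    train_seqs: SequenceSet
    train_annots: AnnotationTable
    test_seqs: SequenceSet
    test_annots: AnnotationTable
    threshold: Optional[float] = None
    train_log: ProvenanceLog = field(default_factory=ProvenanceLog)
    test_log: ProvenanceLog = field(default_factory=ProvenanceLog)

    def __post_init__(self):
        for seqs, annots, split in (
            (self.train_seqs, self.train_annots, "train"),
            (self.test_seqs, self.test_annots, "test"),
        ):
            extra = set(annots.entries) - set(seqs.records)
            if extra:
                raise ValueError(
                    f"{split}: annotated proteins without sequences: {sorted(extra)[:5]}"
                )


# ---------------------------------------------------------------------------
# per-split steps
# ---------------------------------------------------------------------------

def drop_non_enzymes(
    seqs: SequenceSet, annots: AnnotationTable, log: Optional[ProvenanceLog] = None
) -> Tuple[SequenceSet, AnnotationTable]:
    """Keep exactly the proteins carrying at least one EC annotation."""
    keep = [pid for pid in seqs.records if pid in annots.entries]
    out_seqs = seqs.restrict(keep)
    out_annots = annots.restrict(keep)
    if log is not None:
        log.record("drop_non_enzymes", len(seqs), len(out_seqs))
    return out_seqs, out_annots


def dedup_sequences(
    seqs: SequenceSet, annots: AnnotationTable, log: Optional[ProvenanceLog] = None
) -> Tuple[SequenceSet, AnnotationTable]:
    """Collapse identical sequence strings within a split.

    The representative is the lexicographically smallest identifier; EC
    annotations of collapsed records merge by union.
    """
    by_seq: Dict[str, List[str]] = {}
    for pid, seq in seqs.records.items():
        by_seq.setdefault(seq, []).append(pid)
    out_seqs: Dict[str, str] = {}
    out_annots: Dict[str, frozenset] = {}
    for seq, pids in by_seq.items():
        rep = min(pids)
        out_seqs[rep] = seq
        merged = frozenset().union(
            *[annots.entries.get(p, frozenset()) for p in pids]
        )
        if merged:
            out_annots[rep] = merged
    if log is not None:
        log.record("dedup_sequences", len(seqs), len(out_seqs))
    return SequenceSet(out_seqs), AnnotationTable(out_annots)


# ---------------------------------------------------------------------------
# clustering backends
# ---------------------------------------------------------------------------

def percent_identity(a: str, b: str) -> float:
    """Global-alignment percent identity: matches / alignment length."""
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    matched = nice["matched_aligned"]
    matches = matched.count("|")
    return 100.0 * matches / len(matched)


def _kmers(seq: str, k: int) -> Set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def builtin_cluster(
    seqs: SequenceSet, identity: float, k: int = 4
) -> Dict[str, str]:
    """Greedy incremental single-linkage-to-representative clustering.

    Sequences are visited by descending length (identifier as tie-break);
    each joins the first existing representative whose percent identity
    reaches ``identity``, else founds its own cluster.  A k-mer containment
    screen skips hopeless pairs before the verification alignment
    (containment below half the identity fraction cannot reach the
    threshold for near-global alignments at small k).  Deterministic.

    Returns a mapping sequence id -> representative id.
    """
    if not 0 < identity <= 100:
        raise ValueError(f"identity must be in (0, 100], got {identity}")
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    order = sorted(seqs.records, key=lambda p: (-len(seqs.records[p]), p))
    reps: List[str] = []
    rep_kmers: Dict[str, Set[str]] = {}
    assignment: Dict[str, str] = {}
    screen = max(0.0, identity / 100.0 - 0.5)
    for pid in order:
        seq = seqs.records[pid]
        km = _kmers(seq, k)
        joined = False
        for rep in reps:
            shared = len(km & rep_kmers[rep])
            if km and shared / len(km) < screen:
                continue
            if percent_identity(seq, seqs.records[rep]) >= identity:
                assignment[pid] = rep
                joined = True
                break
        if not joined:
            reps.append(pid)
            rep_kmers[pid] = km
            assignment[pid] = pid
    return assignment


def read_cluster_tsv(path) -> Dict[str, str]:
    """Adapter for the two-column (representative, member) TSV emitted by
    standard external clusterers."""
    assignment: Dict[str, str] = {}
    with Path(path).open() as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            rep, member = parts
            assignment[member] = rep
    return assignment


Clusterer = Callable[[SequenceSet, float], Dict[str, str]]


def filter_similar(
    train: Tuple[SequenceSet, AnnotationTable],
    test: Tuple[SequenceSet, AnnotationTable],
    threshold: float,
    clusterer: Optional[Clusterer] = None,
    log: Optional[ProvenanceLog] = None,
) -> Tuple[SequenceSet, AnnotationTable]:
    """Remove training sequences co-clustered with any test sequence.

    The union of train + test is clustered at ``threshold`` percent
    identity; every training sequence sharing a cluster with a test
    sequence is dropped.  The test split is never modified.  Identifier
    collisions between splits are disambiguated internally.
    """
    train_seqs, train_annots = train
    test_seqs, _ = test
    clusterer = clusterer or builtin_cluster

    union = SequenceSet(
        {f"tr|{p}": s for p, s in train_seqs.records.items()}
        | {f"te|{p}": s for p, s in test_seqs.records.items()}
    )
    assignment = clusterer(union, threshold)
    test_clusters = {
        assignment[pid] for pid in assignment if pid.startswith("te|")
    }
    keep = [
        pid for pid in train_seqs.records
        if assignment[f"tr|{pid}"] not in test_clusters
    ]
    out_seqs = train_seqs.restrict(keep)
    out_annots = train_annots.restrict(keep)
    if log is not None:
        log.record("filter_similar", len(train_seqs), len(out_seqs),
                   threshold=threshold,
                   clusterer=getattr(clusterer, "__name__", str(clusterer)))
    return out_seqs, out_annots


# ---------------------------------------------------------------------------
# pluggable hooks (structure availability, metadata)
# ---------------------------------------------------------------------------

def structure_filter(
    seqs: SequenceSet,
    annots: AnnotationTable,
    predicate: Iterable[str],
    log: Optional[ProvenanceLog] = None,
) -> Tuple[SequenceSet, AnnotationTable]:
    """Keep only proteins in the supplied id list (e.g. those with an
    available predicted 3D structure)."""
    allowed = set(predicate)
    keep = [pid for pid in seqs.records if pid in allowed]
    out_seqs = seqs.restrict(keep)
    out_annots = annots.restrict(keep)
    if log is not None:
        log.record("structure_filter", len(seqs), len(out_seqs))
    return out_seqs, out_annots


def attach_metadata(
    annots: AnnotationTable, mapping: Mapping[str, str]
) -> Dict[str, dict]:
    """Attach external per-protein metadata (e.g. GO terms, taxonomic
    groups) verbatim; mapping rows for unknown proteins are logged and
    ignored."""
    import logging

    logger = logging.getLogger(__name__)
    enriched: Dict[str, dict] = {}
    unknown = 0
    for pid, labels in annots.entries.items():
        enriched[pid] = {"ec_numbers": sorted(str(e) for e in labels)}
    for pid, value in mapping.items():
        if pid in enriched:
            enriched[pid]["metadata"] = value
        else:
            unknown += 1
    if unknown:
        logger.warning("attach_metadata: %d mapping rows reference unknown proteins",
                       unknown)
    return enriched


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def curate(
    train_seqs: SequenceSet,
    train_annots: AnnotationTable,
    test_seqs: SequenceSet,
    test_annots: AnnotationTable,
    threshold: float = 100.0,
    clusterer: Optional[Clusterer] = None,
) -> DatasetBundle:
    """Run the full curation pipeline at one similarity threshold."""
    train_log, test_log = ProvenanceLog(), ProvenanceLog()
    tr_s, tr_a = drop_non_enzymes(train_seqs, train_annots, train_log)
    tr_s, tr_a = dedup_sequences(tr_s, tr_a, train_log)
    te_s, te_a = drop_non_enzymes(test_seqs, test_annots, test_log)
    te_s, te_a = dedup_sequences(te_s, te_a, test_log)
    tr_s, tr_a = filter_similar(
        (tr_s, tr_a), (te_s, te_a), threshold, clusterer=clusterer, log=train_log
    )
    return DatasetBundle(
        train_seqs=tr_s, train_annots=tr_a,
        test_seqs=te_s, test_annots=te_a,
        threshold=threshold, train_log=train_log, test_log=test_log,
    )
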