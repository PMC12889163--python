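"""Readers and writers for every external artifact the framework touches.

Canonical on-disk dialects:

* **TSV** for all tables (EC lists use ``;`` internally and protein
  descriptions may contain commas, so tab-separated is the safe choice).
* **FASTA** for protein sequences (via Biopython).
* **JSON** for metric reports, sunburst trees, and run manifests.

All readers are strict by default: a malformed row raises a
:class:`FormatError` carrying the line number.  ``lenient=True`` logs and
skips bad rows instead.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Set, Tuple

from Bio import SeqIO

from .ec_core import ECLabel, parse_ec

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "AnnotationTable",
    "PredictionTable",
    "SequenceSet",
    "read_annotations",
    "write_annotations",
    "read_predictions",
    "write_predictions",
    "read_fasta",
    "write_fasta",
    "write_report",
    "read_report",
    "write_sunburst",
    "write_sunburst_diff",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """A malformed input row; carries the file path and 1-based line number."""

    def __init__(self, path, line_no: Optional[int], message: str):
        self.path = str(path)
        self.line_no = line_no
        where = f"{path}" if line_no is None else f"{path}:{line_no}"
        super().__init__(f"{where}: {message}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationTable:
    """Ground-truth annotations: protein identifier -> non-empty set of EC labels."""

    entries: Dict[str, FrozenSet[ECLabel]]

    def __post_init__(self):
        for pid, labels in self.entries.items():
            if not labels:
                raise ValueError(f"protein {pid!r} has an empty label set")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pid: str) -> bool:
        return pid in self.entries

    def proteins(self) -> List[str]:
        return list(self.entries)

    def restrict(self, proteins) -> "AnnotationTable":
        keep = set(proteins)
        return AnnotationTable({p: s for p, s in self.entries.items() if p in keep})


@dataclass
class PredictionTable:
    """One model's scored EC predictions.

    ``entries`` maps protein -> list of (label, score) pairs, score in [0, 1],
    at most one pair per (protein, label).  A protein with no prediction is
    simply absent.
    """

    model_name: str
    entries: Dict[str, List[Tuple[ECLabel, float]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def proteins(self) -> List[str]:
        return list(self.entries)

    def scores_for(self, protein: str) -> Dict[ECLabel, float]:
        return dict(self.entries.get(protein, []))

    def top_label(self, protein: str) -> Optional[ECLabel]:
        """Highest-scoring label; score ties broken by smallest canonical
        EC string; ``None`` if the protein is absent or has no entries."""
        pairs = self.entries.get(protein)
        if not pairs:
            return None
        return min(pairs, key=lambda p: (-p[1], str(p[0])))[0]


@dataclass(frozen=True)
class SequenceSet:
    """Amino-acid sequences keyed by unique identifier."""

    records: Dict[str, str]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pid: str) -> bool:
        return pid in self.records

    def restrict(self, proteins) -> "SequenceSet":
        keep = set(proteins)
        return SequenceSet({p: s for p, s in self.records.items() if p in keep})


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _iter_tsv(path, expected_cols: List[str]):
    """Yield (line_no, fields) for each data row, validating the header."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header:
            raise FormatError(path, None, "empty file")
        cols = header.rstrip("\n").split("\t")
        missing = [c for c in expected_cols if c not in cols]
        if missing:
            raise FormatError(path, 1, f"missing columns {missing} (found {cols})")
        idx = [cols.index(c) for c in expected_cols]
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(cols):
                raise FormatError(path, line_no, f"expected {len(cols)} columns, got {len(fields)}")
            yield line_no, [fields[i] for i in idx]


def read_annotations(path, lenient: bool = False) -> AnnotationTable:
    """Read a TSV with columns ``protein_id`` and ``ec_numbers``
    (semicolon-separated EC labels).  Duplicate protein rows merge by union."""
    entries: Dict[str, Set[ECLabel]] = {}
    for line_no, (pid, cell) in _iter_tsv(path, ["protein_id", "ec_numbers"]):
        try:
            if not pid:
                raise ValueError("empty protein identifier")
            labels = {parse_ec(tok) for tok in cell.split(";") if tok.strip()}
            if not labels:
                raise ValueError(f"no EC labels in cell {cell!r}")
        except ValueError as exc:
            if lenient:
                logger.warning("skipping %s:%d: %s", path, line_no, exc)
                continue
            raise FormatError(path, line_no, str(exc)) from exc
        entries.setdefault(pid, set()).update(labels)
    return AnnotationTable({p: frozenset(s) for p, s in entries.items()})


def write_annotations(table: AnnotationTable, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein_id\tec_numbers\n")
        for pid in sorted(table.entries):
            ecs = ";".join(sorted(str(e) for e in table.entries[pid]))
            fh.write(f"{pid}\t{ecs}\n")


def read_predictions(path, model_name: str, lenient: bool = False) -> PredictionTable:
    """Read a TSV with columns ``protein_id``, ``ec_number``, ``score``.

    Scores must lie in [0, 1]; duplicate (protein, EC) rows keep the
    maximum score.
    """
    best: Dict[str, Dict[ECLabel, float]] = {}
    for line_no, (pid, ec_text, score_text) in _iter_tsv(
        path, ["protein_id", "ec_number", "score"]
    ):
        try:
            label = parse_ec(ec_text)
            score = float(score_text)
            if math.isnan(score) or not 0.0 <= score <= 1.0:
                raise ValueError(f"score {score_text!r} outside [0, 1]")
        except ValueError as exc:
            if lenient:
                logger.warning("skipping %s:%d: %s", path, line_no, exc)
                continue
            raise FormatError(path, line_no, str(exc)) from exc
        slot = best.setdefault(pid, {})
        slot[label] = max(score, slot.get(label, 0.0))
    entries = {
        pid: sorted(d.items(), key=lambda p: (-p[1], str(p[0])))
        for pid, d in best.items()
    }
    return PredictionTable(model_name=model_name, entries=entries)


def write_predictions(table: PredictionTable, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("protein_id\tec_number\tscore\n")
        for pid in sorted(table.entries):
            for label, score in table.entries[pid]:
                fh.write(f"{pid}\t{label}\t{score:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> SequenceSet:
    """Read a multi-line FASTA file into a :class:`SequenceSet`.

    Duplicate identifiers and empty files are errors; sequences are
    upper-cased and must be non-empty.
    """
    records: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(path, None, f"duplicate FASTA identifier {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(path, None, f"empty sequence for {rec.id!r}")
        records[rec.id] = seq
    if not records:
        raise FormatError(path, None, "empty FASTA file")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet, path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for pid in sorted(seqs.records):
            fh.write(f">{pid}\n")
            s = seqs.records[pid]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# metric reports
# ---------------------------------------------------------------------------

def write_report(report, path_prefix) -> None:
    """Write a metrics report as ``<prefix>.json`` (full structure) and
    ``<prefix>.tsv`` (flat per-class rows).

    ``report`` is any object with a ``to_dict()`` method following the
    MetricsReport layout (see :mod:`ecbench.exact_eval`).
    """
    prefix = Path(path_prefix)
    doc = report.to_dict()
    with prefix.with_suffix(".json").open("w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with prefix.with_suffix(".tsv").open("w") as fh:
        fh.write("level\tec\tsupport\ttp\tfp\tfn\tprecision\trecall\tf1\n")
        for level_doc in doc["levels"]:
            for row in level_doc["per_class"]:
                fh.write(
                    "{}\t{}\t{}\t{}\t{}\t{}\t{:.17g}\t{:.17g}\t{:.17g}\n".format(
                        level_doc["level"], row["ec"], row["support"], row["tp"],
                        row["fp"], row["fn"], row["precision"], row["recall"], row["f1"],
                    )
                )


def read_report(path_prefix) -> dict:
    """Read back the JSON half of a report written by :func:`write_report`."""
    with Path(path_prefix).with_suffix(".json").open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# sunburst trees
# ---------------------------------------------------------------------------

def _sunburst_tree(per_class: Mapping[ECLabel, Mapping[str, float]]) -> dict:
    """Arrange per-node stats into the nested EC hierarchy.

    Each node carries ``label`` (canonical EC text of the truncation),
    ``support``, ``f1`` and ``children``.  Root children are the top-level
    EC classes present.
    """
    root = {"label": "EC", "support": None, "f1": None, "children": []}
    index = {(): root}

    def node_for(prefix: Tuple[str, ...]) -> dict:
        if prefix in index:
            return index[prefix]
        parent = node_for(prefix[:-1])
        text = ".".join(prefix) + ".-" * (4 - len(prefix))
        node = {"label": text, "support": 0, "f1": 0.0, "children": []}
        parent["children"].append(node)
        index[prefix] = node
        return node

    for label in sorted(per_class, key=str):
        prefix = label.tokens[: label.depth]
        node = node_for(prefix)
        stats = per_class[label]
        node["support"] = int(stats["support"])
        node["f1"] = float(stats["f1"])

    def sort_children(node):
        node["children"].sort(key=lambda c: c["label"])
        for c in node["children"]:
            sort_children(c)

    sort_children(root)
    return root


def write_sunburst(per_class: Mapping[ECLabel, Mapping[str, float]], path) -> None:
    """Emit the per-EC-node F1/support hierarchy as nested JSON, consumable
    by any sunburst renderer."""
    with Path(path).open("w") as fh:
        json.dump(_sunburst_tree(per_class), fh, indent=2)
        fh.write("\n")


def write_sunburst_diff(
    per_class_a: Mapping[ECLabel, Mapping[str, float]],
    per_class_b: Mapping[ECLabel, Mapping[str, float]],
    path,
) -> None:
    """Difference tree: per-node F1 of model A minus model B.

    Nodes absent in one model count as F1 = 0 there; support is the
    maximum of the two supports.
    """
    keys = set(per_class_a) | set(per_class_b)
    diff = {}
    for k in keys:
        fa = per_class_a.get(k, {}).get("f1", 0.0)
        fb = per_class_b.get(k, {}).get("f1", 0.0)
        sa = per_class_a.get(k, {}).get("support", 0)
        sb = per_class_b.get(k, {}).get("support", 0)
        diff[k] = {"support": max(sa, sb), "f1": fa - fb}
    with Path(path).open("w") as fh:
        json.dump(_sunburst_tree(diff), fh, indent=2)
        fh.write("\n")
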