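"""Ensemble combiners: majority voting and stacking.

*Majority voting* takes each base model's top label per protein and emits
every modal label (ties emit all tied labels, which is how voting ensembles
end up recommending additional EC numbers).  *Stacking* concatenates the
base models' score vectors over a shared label space into features for a
per-class regularized linear meta-classifier, fitted on a validation split
and applied to test proteins.

The meta-model family is pluggable; the default is one-vs-rest L2 logistic
regression, chosen for determinism and speed.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression

from .ec_core import ECLabel
from .io_formats import AnnotationTable, PredictionTable

__all__ = ["majority_vote", "StackerModel", "fit_stacker", "apply_stacker"]


def majority_vote(
    base: Sequence[PredictionTable],
    denominator: str = "voters",
    name: str = "majority_vote",
) -> PredictionTable:
    """Combine base models by their most frequently predicted top label.

    Per protein, each base model casts its top label as a vote (abstaining
    models cast none).  Every modal label (all labels tied at the maximum
    vote count) is emitted with score ``count / n``, where ``n`` is the
    number of voting models (``denominator="voters"``, default) or all
    base models (``denominator="all"``).
    """
    if len(base) < 2:
        raise ValueError("majority_vote needs at least 2 base models")
    if denominator not in ("voters", "all"):
        raise ValueError(f"unknown denominator {denominator!r}")
    proteins = set()
    for table in base:
        proteins.update(table.entries)
    entries: Dict[str, List[Tuple[ECLabel, float]]] = {}
    for pid in proteins:
        votes = [t.top_label(pid) for t in base]
        votes = [v for v in votes if v is not None]
        if not votes:
            continue
        counts: Dict[ECLabel, int] = {}
        for v in votes:
            counts[v] = counts.get(v, 0) + 1
        top = max(counts.values())
        n = len(votes) if denominator == "voters" else len(base)
        entries[pid] = sorted(
            ((ec, c / n) for ec, c in counts.items() if c == top),
            key=lambda p: str(p[0]),
        )
    return PredictionTable(model_name=name, entries=entries)


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

@dataclass
class StackerModel:
    """Fitted stacking meta-model.

    ``label_space`` orders both the feature layout (each base model owns a
    contiguous slice of width ``len(label_space)``) and the output space:
    labels unseen in validation are never emitted.
    """

    label_space: List[ECLabel]
    base_model_names: List[str]
    seed: int
    classifiers: Dict[ECLabel, object] = field(default_factory=dict)
    constant_scores: Dict[ECLabel, float] = field(default_factory=dict)
    class_priors: Dict[ECLabel, float] = field(default_factory=dict)
    emit_floor: float = 0.01

    @property
    def feature_width(self) -> int:
        return len(self.base_model_names) * len(self.label_space)

    def feature_slice(self, model_name: str) -> slice:
        i = self.base_model_names.index(model_name)
        w = len(self.label_space)
        return slice(i * w, (i + 1) * w)

    # persistence: binary artifact + JSON sidecar handled by cli_report
    def save(self, path) -> None:
        with Path(path).open("wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "StackerModel":
        with Path(path).open("rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not contain a StackerModel")
        return model


def _feature_matrix(
    base: Sequence[PredictionTable],
    proteins: Sequence[str],
    label_space: Sequence[ECLabel],
) -> np.ndarray:
    """Concatenate each base model's score vector; missing scores are 0."""
    col = {ec: j for j, ec in enumerate(label_space)}
    w = len(label_space)
    X = np.zeros((len(proteins), len(base) * w))
    for b, table in enumerate(base):
        off = b * w
        for i, pid in enumerate(proteins):
            for ec, score in table.entries.get(pid, ()):
                j = col.get(ec)
                if j is not None:
                    X[i, off + j] = score
    return X


def fit_stacker(
    base_on_validation: Sequence[PredictionTable],
    validation_truth: AnnotationTable,
    seed: int = 17,
    C: float = 1000.0,
) -> StackerModel:
    """Train the stacking meta-model on validation features.

    One L2-regularized logistic regression is fitted per label with at
    least one validation positive (one-vs-rest).  Labels positive for
    every validation protein get a constant score equal to 1; labels with
    no positive are never emitted.  Proteins whose features are all zero
    (every base model abstained) are scored by the validation class
    priors, the intercept-only limit of the meta-model.
    """
    if not base_on_validation:
        raise ValueError("no base models given")
    if len(validation_truth) == 0:
        raise ValueError("empty validation set")

    label_set: Set[ECLabel] = set()
    for table in base_on_validation:
        for pairs in table.entries.values():
            label_set.update(ec for ec, _ in pairs)
    for labels in validation_truth.entries.values():
        label_set.update(labels)
    label_space = sorted(label_set, key=str)
    if not label_space:
        raise ValueError("empty feature space")

    truth_classes = set()
    for labels in validation_truth.entries.values():
        truth_classes.update(labels)
    if len(truth_classes) < 2:
        raise ValueError("validation set has a single class; stacking is degenerate")

    proteins = sorted(validation_truth.entries)
    X = _feature_matrix(base_on_validation, proteins, label_space)

    model = StackerModel(
        label_space=label_space,
        base_model_names=[t.model_name for t in base_on_validation],
        seed=seed,
    )
    n = len(proteins)
    for ec in label_space:
        y = np.array([ec in validation_truth.entries[p] for p in proteins], dtype=int)
        n_pos = int(y.sum())
        model.class_priors[ec] = n_pos / n
        if n_pos == 0:
            continue  # never emitted
        if n_pos == n:
            model.constant_scores[ec] = 1.0
            continue
        clf = LogisticRegression(
            C=C, solver="lbfgs", max_iter=2000, random_state=seed
        )
        clf.fit(X, y)
        model.classifiers[ec] = clf
    return model


def apply_stacker(
    model: StackerModel,
    base_on_test: Sequence[PredictionTable],
    name: str = "stacked",
) -> PredictionTable:
    """Score test proteins with a fitted stacker.

    Base tables may arrive in any order but must carry exactly the model
    names seen at fit time; they are realigned by name.  Output scores are
    per-class probabilities; labels scoring below the emission floor are
    dropped (the argmax label is always kept).
    """
    by_name = {t.model_name: t for t in base_on_test}
    if sorted(by_name) != sorted(model.base_model_names):
        raise ValueError(
            f"base model mismatch: fitted on {model.base_model_names}, "
            f"got {sorted(by_name)}"
        )
    base = [by_name[n] for n in model.base_model_names]

    proteins = sorted(set().union(*[set(t.entries) for t in base])) if base else []
    if not proteins:
        return PredictionTable(model_name=name, entries={})
    X = _feature_matrix(base, proteins, model.label_space)
    zero_rows = ~X.any(axis=1)

    scores = np.zeros((len(proteins), len(model.label_space)))
    for j, ec in enumerate(model.label_space):
        if ec in model.constant_scores:
            scores[:, j] = model.constant_scores[ec]
        elif ec in model.classifiers:
            scores[:, j] = model.classifiers[ec].predict_proba(X)[:, 1]
        # else: no validation positive -> never emitted (stays 0)
    # abstain-everywhere proteins carry no signal: score by class priors
    if zero_rows.any():
        priors = np.array([model.class_priors[ec] for ec in model.label_space])
        emitted = np.array([
            ec in model.constant_scores or ec in model.classifiers
            for ec in model.label_space
        ])
        scores[zero_rows] = priors * emitted

    entries: Dict[str, List[Tuple[ECLabel, float]]] = {}
    for i, pid in enumerate(proteins):
        row = scores[i]
        if not row.any():
            continue
        jmax = int(np.lexsort((np.array([str(e) for e in model.label_space]), -row))[0])
        pairs = [
            (ec, float(row[j]))
            for j, ec in enumerate(model.label_space)
            if row[j] >= model.emit_floor or j == jmax
        ]
        pairs.sort(key=lambda p: (-p[1], str(p[0])))
        entries[pid] = pairs
    return PredictionTable(model_name=name, entries=entries)
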