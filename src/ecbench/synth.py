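"""Synthetic fixture generator.

Emulates the inputs every evaluation task assumes — a hierarchical EC label
space, multi-label enzymes, partial "dash" annotations, per-model accuracy
and coverage profiles, and family-structured toy reactions — so the whole
framework runs and is testable with no external data or models.

Statistical structure:

* the label space is a complete tree (default 4 x 3 x 3 x 4 children per
  level) with a long-tailed geometric frequency distribution over leaves;
* a synthetic model errs *hierarchically*: when it misses at level ``k`` it
  predicts a sibling sharing the first ``k - 1`` levels, so measured
  metrics degrade gracefully with depth exactly as per-level accuracies
  prescribe (P(correct at level k) == designed a_k, a_k non-increasing);
* scores are the designed level-4 accuracy for hits and its complement for
  misses, plus uniform +/-0.1 calibration noise clipped to [0, 1] — enough
  to make threshold learning non-trivial without destroying ranking;
* toy reactions are built per 3-level family from simple valid SMILES
  tokens; level-4 siblings mutate a small fraction of tokens, planting
  within-family reaction similarity above cross-family similarity.

Default rates mirror the benchmark's test conditions: 468 proteins with
roughly two thirds of annotations incomplete.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .ec_core import ECLabel
from .fingerprints import FingerprintBackend, TokenHashFingerprinter
from .io_formats import AnnotationTable, PredictionTable, SequenceSet
from .recommend_eval import ReactionTable

__all__ = ["ModelProfile", "SyntheticSpec", "generate_truth",
           "generate_predictions", "generate_reaction_table"]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: simple, individually valid SMILES molecule tokens for toy reactions
_SMILES_TOKENS = [
    "C", "O", "N", "S", "P", "CC", "CO", "CN", "CS", "C=O", "C#N",
    "CCO", "CCN", "CC=O", "C(=O)O", "CC(=O)O", "CCC", "OCC(O)CO",
]


@dataclass(frozen=True)
class ModelProfile:
    """Designed behaviour of one synthetic prediction model.

    ``per_level_accuracy`` gives the marginal probability that the
    predicted label is correct at each EC level (must be non-increasing:
    correctness at level k implies correctness above).  Errors are drawn
    from siblings at the deepest erred level.
    """

    name: str
    coverage: float = 1.0
    per_level_accuracy: Tuple[float, float, float, float] = (0.95, 0.9, 0.85, 0.8)
    score_noise: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        acc = self.per_level_accuracy
        if len(acc) != 4 or any(not 0.0 <= a <= 1.0 for a in acc):
            raise ValueError("per_level_accuracy needs 4 values in [0, 1]")
        if any(acc[i] < acc[i + 1] for i in range(3)):
            raise ValueError("per_level_accuracy must be non-increasing")


def _default_profiles() -> Tuple[ModelProfile, ...]:
    # a spread of model qualities and coverages, from a strong
    # full-coverage predictor down to a weak sparse one
    return (
        ModelProfile("syn_a", 1.0, (0.95, 0.90, 0.85, 0.80)),
        ModelProfile("syn_b", 0.95, (0.90, 0.85, 0.78, 0.70)),
        ModelProfile("syn_c", 0.9, (0.85, 0.78, 0.70, 0.60)),
        ModelProfile("syn_d", 0.8, (0.80, 0.70, 0.60, 0.50)),
        ModelProfile("syn_e", 0.6, (0.70, 0.60, 0.50, 0.40)),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance."""

    n_proteins: int = 468
    hierarchy_shape: Tuple[int, ...] = (4, 3, 3, 4)
    multi_label_rate: float = 0.1
    incomplete_rate: float = 2 / 3
    model_profiles: Tuple[ModelProfile, ...] = field(default_factory=_default_profiles)
    reaction_family_noise: float = 0.2
    held_out_fraction: float = 0.1
    geometric_q: float = 0.55
    seed: int = 17

    def __post_init__(self):
        if len(self.hierarchy_shape) != 4 or any(c < 1 for c in self.hierarchy_shape):
            raise ValueError("hierarchy_shape needs 4 counts >= 1")
        for rate in (self.multi_label_rate, self.incomplete_rate,
                     self.reaction_family_noise, self.held_out_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if all(c == 1 for c in self.hierarchy_shape):
            raise ValueError("degenerate hierarchy: a single leaf")

    # -- label space --------------------------------------------------------
    def leaves(self) -> List[ECLabel]:
        ranges = [range(1, c + 1) for c in self.hierarchy_shape]
        return [
            ECLabel(tuple(str(t) for t in path))
            for path in itertools.product(*ranges)
        ]

    def leaf_probabilities(self) -> np.ndarray:
        """Long-tailed leaf frequencies: geometric weight per child index at
        every level, multiplied along the path and normalized."""
        probs = []
        for leaf in self.leaves():
            w = 1.0
            for tok in leaf.tokens:
                w *= self.geometric_q ** int(tok)
            probs.append(w)
        arr = np.array(probs)
        return arr / arr.sum()

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with Path(path).open() as fh:
            doc = yaml.safe_load(fh) or {}
        if "model_profiles" in doc:
            doc["model_profiles"] = tuple(
                ModelProfile(
                    name=p["name"],
                    coverage=p.get("coverage", 1.0),
                    per_level_accuracy=tuple(p.get("per_level_accuracy",
                                                   (0.95, 0.9, 0.85, 0.8))),
                    score_noise=p.get("score_noise", 0.1),
                )
                for p in doc["model_profiles"]
            )
        if "hierarchy_shape" in doc:
            doc["hierarchy_shape"] = tuple(doc["hierarchy_shape"])
        return cls(**doc)


# ---------------------------------------------------------------------------

def generate_truth(spec: SyntheticSpec) -> Tuple[SequenceSet, AnnotationTable]:
    """Random sequences (length 80-400) with long-tailed hierarchical labels.

    Each protein gets one leaf label, a second distinct leaf with
    probability ``multi_label_rate``, and each label is independently
    truncated to a random depth 1-3 with probability ``incomplete_rate``.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    leaves = spec.leaves()
    probs = spec.leaf_probabilities()
    width = len(str(spec.n_proteins))
    records: Dict[str, str] = {}
    entries: Dict[str, frozenset] = {}
    for i in range(spec.n_proteins):
        pid = f"SYN{i:0{width}d}"
        length = int(rng.integers(80, 401))
        records[pid] = "".join(rng.choice(_AMINO_ACIDS, size=length))
        labels = [leaves[rng.choice(len(leaves), p=probs)]]
        if rng.random() < spec.multi_label_rate:
            other = leaves[rng.choice(len(leaves), p=probs)]
            while other == labels[0]:
                other = leaves[rng.choice(len(leaves), p=probs)]
            labels.append(other)
        final = []
        for ec in labels:
            if rng.random() < spec.incomplete_rate:
                depth = int(rng.integers(1, 4))
                final.append(ec.truncate(depth))
            else:
                final.append(ec)
        entries[pid] = frozenset(final)
    return SequenceSet(records), AnnotationTable(entries)


def _latent_completion(pid: str, ec: ECLabel, spec: SyntheticSpec) -> ECLabel:
    """The latent full label behind a partial annotation.

    Derived deterministically from (protein, label, spec seed) so every
    model profile targets the same underlying function — a partially
    annotated enzyme still catalyzes one definite reaction.
    """
    sub = zlib.crc32(f"{pid}|{ec}".encode())
    rng = np.random.default_rng((spec.seed, 2, sub))
    tokens = list(ec.tokens[: ec.depth])
    for level in range(ec.depth, 4):
        tokens.append(str(int(rng.integers(1, spec.hierarchy_shape[level] + 1))))
    return ECLabel(tokens)


def _err_sibling(true: ECLabel, level: int, spec: SyntheticSpec, rng) -> ECLabel:
    """A label sharing the first ``level - 1`` tokens but differing at
    ``level``, with random tokens below."""
    n_children = spec.hierarchy_shape[level - 1]
    if n_children < 2:
        # no sibling exists at this level; err one level deeper if possible
        if level < 4:
            return _err_sibling(true, level + 1, spec, rng)
        return true  # degenerate tree: cannot err at all
    true_tok = int(true.tokens[level - 1])
    wrong = true_tok
    while wrong == true_tok:
        wrong = int(rng.integers(1, n_children + 1))
    tokens = list(true.tokens[: level - 1]) + [str(wrong)]
    for lv in range(level, 4):
        tokens.append(str(int(rng.integers(1, spec.hierarchy_shape[lv] + 1))))
    return ECLabel(tokens)


def generate_predictions(
    spec: SyntheticSpec, truth: AnnotationTable
) -> List[PredictionTable]:
    """One scored prediction table per model profile.

    Per covered protein the model targets one randomly chosen true label
    (its latent completion when partial) and emits a single prediction
    whose erred level follows the profile's per-level accuracies.
    """
    tables = []
    for m_idx, profile in enumerate(spec.model_profiles):
        rng = np.random.default_rng((spec.seed, 1000 + m_idx))
        a = profile.per_level_accuracy
        # P(first error at level k) = a_{k-1} - a_k, P(no error) = a_4
        err_probs = [1 - a[0], a[0] - a[1], a[1] - a[2], a[2] - a[3], a[3]]
        entries: Dict[str, list] = {}
        for pid in sorted(truth.entries):
            if rng.random() >= profile.coverage:
                continue
            labels = sorted(truth.entries[pid], key=str)
            target = labels[int(rng.integers(0, len(labels)))]
            if not target.is_complete:
                target = _latent_completion(pid, target, spec)
            choice = int(rng.choice(5, p=err_probs))
            if choice == 4:
                pred = target
            else:
                pred = _err_sibling(target, choice + 1, spec, rng)
            hit = pred == target
            base = a[3] if hit else 1.0 - a[3]
            score = float(np.clip(
                base + rng.uniform(-profile.score_noise, profile.score_noise),
                0.0, 1.0,
            ))
            entries[pid] = [(pred, score)]
        tables.append(PredictionTable(model_name=profile.name, entries=entries))
    return tables


def generate_reaction_table(
    spec: SyntheticSpec, backend: Optional[FingerprintBackend] = None
) -> ReactionTable:
    """Family-structured toy reactions over the complete label space.

    One base reaction (4 reactant + 4 product tokens) per 3-level family;
    each level-4 child mutates ``reaction_family_noise`` of the tokens.  A
    ``held_out_fraction`` of complete ECs get no record, exercising the
    surrogate-sampling fallback.
    """
    rng = np.random.default_rng((spec.seed, 7))
    table = ReactionTable(backend=backend or TokenHashFingerprinter())
    leaves = spec.leaves()
    held_out = set()
    if spec.held_out_fraction > 0:
        n_hold = int(round(spec.held_out_fraction * len(leaves)))
        if n_hold:
            idx = rng.choice(len(leaves), size=n_hold, replace=False)
            held_out = {leaves[i] for i in idx}

    families: Dict[Tuple[str, ...], List[str]] = {}
    for leaf in leaves:
        fam = leaf.tokens[:3]
        if fam not in families:
            families[fam] = list(rng.choice(_SMILES_TOKENS, size=8))
    n_tokens = 8
    n_mut = int(round(spec.reaction_family_noise * n_tokens))
    for leaf in leaves:
        base = list(families[leaf.tokens[:3]])
        if n_mut:
            pos = rng.choice(n_tokens, size=n_mut, replace=False)
            for p in pos:
                repl = base[p]
                while repl == base[p]:
                    repl = str(rng.choice(_SMILES_TOKENS))
                base[p] = repl
        reaction = ".".join(base[:4]) + ">>" + ".".join(base[4:])
        if leaf in held_out:
            continue
        table.add(leaf, reaction)
    return table
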