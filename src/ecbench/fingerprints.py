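"""Reaction fingerprint backends.

A backend turns a reaction string (``reactants>>products``, molecules
``.``-separated, SMILES) into a fixed-size vector comparable by Tanimoto
(intersection over union) similarity.  Two backends ship:

* :class:`RDKitDifferenceFingerprinter` — the production backend: RDKit's
  chemical difference fingerprint for reactions.
* :class:`TokenHashFingerprinter` — a deterministic, chemistry-free
  backend hashing molecule tokens into a bit space; the default for tests
  and environments without a cheminformatics stack.

Both are pluggable behind the same two-method contract
(``fingerprint(reaction) -> fp``, ``tanimoto(fp_a, fp_b) -> float``).
"""

from __future__ import annotations

import hashlib
from typing import FrozenSet, Protocol

__all__ = [
    "FingerprintBackend",
    "TokenHashFingerprinter",
    "RDKitDifferenceFingerprinter",
    "get_backend",
]


class FingerprintBackend(Protocol):
    name: str

    def fingerprint(self, reaction: str):
        ...

    def tanimoto(self, fp_a, fp_b) -> float:
        ...


def _split_reaction(reaction: str):
    if ">>" not in reaction:
        raise ValueError(f"reaction must contain '>>': {reaction!r}")
    left, right = reaction.split(">>", 1)
    reactants = [m for m in left.split(".") if m]
    products = [m for m in right.split(".") if m]
    if not reactants or not products:
        raise ValueError(f"reaction needs reactants and products: {reaction!r}")
    return reactants, products


class TokenHashFingerprinter:
    """Hash each molecule token (tagged by side) into an ``n_bits`` space.

    The fingerprint is the set of active bit indices; Tanimoto is the
    Jaccard index of those sets.  Hashing uses SHA-1, so fingerprints are
    stable across processes and platforms.
    """

    name = "token_hash"

    def __init__(self, n_bits: int = 2048):
        self.n_bits = n_bits

    def _bit(self, token: str) -> int:
        digest = hashlib.sha1(token.encode()).digest()
        return int.from_bytes(digest[:8], "big") % self.n_bits

    def fingerprint(self, reaction: str) -> FrozenSet[int]:
        reactants, products = _split_reaction(reaction)
        bits = {self._bit("r:" + m) for m in reactants}
        bits |= {self._bit("p:" + m) for m in products}
        return frozenset(bits)

    def tanimoto(self, fp_a: FrozenSet[int], fp_b: FrozenSet[int]) -> float:
        union = len(fp_a | fp_b)
        if union == 0:
            return 1.0  # two empty fingerprints are indistinguishable
        return len(fp_a & fp_b) / union


class RDKitDifferenceFingerprinter:
    """RDKit chemical difference fingerprint for reactions.

    Requires the optional ``rdkit`` dependency (``pip install
    ecbench[chem]``).
    """

    name = "rdkit_difference"

    def __init__(self):
        from rdkit.Chem import rdChemReactions  # deferred heavy import
        from rdkit import DataStructs

        self._rdChemReactions = rdChemReactions
        self._DataStructs = DataStructs

    def fingerprint(self, reaction: str):
        _split_reaction(reaction)  # uniform validation/error message
        rxn = self._rdChemReactions.ReactionFromSmarts(reaction, useSmiles=True)
        if rxn is None:
            raise ValueError(f"RDKit could not parse reaction {reaction!r}")
        return self._rdChemReactions.CreateDifferenceFingerprintForReaction(rxn)

    def tanimoto(self, fp_a, fp_b) -> float:
        if fp_a.GetTotalVal() == 0 and fp_b.GetTotalVal() == 0:
            return 1.0
        return float(self._DataStructs.TanimotoSimilarity(fp_a, fp_b))


def get_backend(name: str) -> FingerprintBackend:
    """Backend factory for CLI/config use (``token_hash`` or ``rdkit``)."""
    if name == "token_hash":
        return TokenHashFingerprinter()
    if name in ("rdkit", "rdkit_difference"):
        return RDKitDifferenceFingerprinter()
    raise ValueError(f"unknown fingerprint backend {name!r}")
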