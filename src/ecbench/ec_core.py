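"""Enzyme Commission (EC) label representation and hierarchy operations.

An EC number is a four-level hierarchical identifier
(class.subclass.sub-subclass.serial, e.g. ``1.1.1.1``) classifying an enzyme
by the reaction it catalyzes.  Partially annotated enzymes carry trailing
undefined levels written as dashes (``1.1.-.-``).  Preliminary serial numbers
assigned before official registration are written ``n<integer>`` (e.g.
``1.1.1.n5``) and are treated here as opaque, distinct level-4 tokens.

Every other module builds on :class:`ECLabel`; equality and hashing use the
canonical dotted text form.
"""

from __future__ import annotations

import re
from functools import total_ordering
from typing import Iterable

__all__ = ["ECLabel", "UNDEFINED", "parse_ec", "truncate", "completes"]

#: Sentinel rendering of an undefined level in the canonical text form.
UNDEFINED = "-"

_TOKEN_RE = re.compile(r"^(?:\d+|n\d+)$")


@total_ordering
class ECLabel:
    """A four-level EC label with a contiguous defined prefix.

    Parameters
    ----------
    tokens
        Exactly four level tokens.  Each token is a string: a positive
        integer (``"1"``), a preliminary token (``"n5"``), or ``"-"``
        (undefined).  Defined tokens must form a contiguous prefix.

    Attributes
    ----------
    tokens : tuple of str
        The four level tokens.
    depth : int
        Number of leading defined tokens, 0-4.  ``"1.1.-.-"`` has depth 2.
    """

    __slots__ = ("tokens", "depth", "_text")

    def __init__(self, tokens: Iterable[str]):
        toks = tuple(str(t) for t in tokens)
        if len(toks) != 4:
            raise ValueError(f"EC label needs exactly 4 tokens, got {len(toks)}")
        depth = 0
        seen_undef = False
        for tok in toks:
            if tok == UNDEFINED:
                seen_undef = True
            else:
                if not _TOKEN_RE.match(tok):
                    raise ValueError(f"malformed EC token {tok!r}")
                if int(tok.lstrip("n")) <= 0 and not tok.startswith("n"):
                    raise ValueError(f"EC token must be positive: {tok!r}")
                if seen_undef:
                    raise ValueError(
                        f"non-contiguous EC prefix: defined token {tok!r} "
                        "after an undefined level"
                    )
                depth += 1
        object.__setattr__(self, "tokens", toks)
        object.__setattr__(self, "depth", depth)
        object.__setattr__(self, "_text", ".".join(toks))

    def __setattr__(self, name, value):  # immutable
        raise AttributeError("ECLabel is immutable")

    # -- canonical form -----------------------------------------------------
    def __str__(self) -> str:
        return self._text

    def __repr__(self) -> str:
        return f"ECLabel({self._text!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, ECLabel):
            return self._text == other._text
        return NotImplemented

    def __lt__(self, other) -> bool:
        if isinstance(other, ECLabel):
            return self._text < other._text
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._text)

    # -- hierarchy ----------------------------------------------------------
    @property
    def is_complete(self) -> bool:
        """True when all four levels are defined."""
        return self.depth == 4

    def truncate(self, level: int) -> "ECLabel":
        """Keep at most ``level`` defined levels, padding with ``-``.

        The result's depth is ``min(level, self.depth)``; truncating cannot
        invent definition below the label's own depth.
        """
        if not 1 <= level <= 4:
            raise ValueError(f"level must be in 1..4, got {level}")
        keep = min(level, self.depth)
        return ECLabel(self.tokens[:keep] + (UNDEFINED,) * (4 - keep))

    def completes(self, partial: "ECLabel") -> bool:
        """True iff this is a complete label extending ``partial``'s prefix."""
        return (
            self.depth == 4
            and self.tokens[: partial.depth] == partial.tokens[: partial.depth]
        )

    def parent_prefix(self, level: int) -> tuple:
        """The first ``level`` tokens (may include undefined padding)."""
        return self.tokens[:level]


def parse_ec(text: str) -> ECLabel:
    """Parse an EC number from its dotted text form.

    Whitespace is trimmed.  Fewer than four dot-separated fields are
    right-padded with undefined levels, so ``"1.1.1"`` parses as
    ``1.1.1.-`` (some annotation sources omit trailing dashes).

    Raises
    ------
    ValueError
        On empty input, malformed tokens, more than four fields, or a
        defined token appearing after an undefined one.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty EC label")
    fields = [f.strip() for f in text.split(".")]
    if len(fields) > 4:
        raise ValueError(f"EC label has more than 4 levels: {text!r}")
    fields += [UNDEFINED] * (4 - len(fields))
    return ECLabel(fields)


def truncate(ec: ECLabel, level: int) -> ECLabel:
    """Functional form of :meth:`ECLabel.truncate`."""
    return ec.truncate(level)


def completes(candidate: ECLabel, partial: ECLabel) -> bool:
    """Functional form of :meth:`ECLabel.completes`."""
    return candidate.completes(partial)
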