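"""Generalized subset-seed patterns.

A pattern assigns to each seed position a *partial equivalence relation* on
the DNA letters: a symmetric relation that is reflexive exactly on the
letters it allows.  This unifies word-restricted seeding with spaced and
subset seeds: a position may restrict which letters can occur at all (e.g.
purines only) and, independently, which letter pairs count as matching.

Symbol semantics (upper case restricts, lower case forgives):

=========  =============================  ==========================
symbol     allowed letters                matching pairs
=========  =============================  ==========================
A C G T    that letter only               the identity pair
N          any                            equal letters
n          any                            any pair
R          a, g                           a:a, g:g
r          a, g                           a:a, g:g, a:g, g:a
Y          c, t                           c:c, t:t
y          c, t                           c:c, t:t, c:t, t:c
@          any                            equal letters or transitions
=========  =============================  ==========================

Two length-independent figures of merit follow from hit probabilities in
random i.i.d. sequences: *sparsity* = 1 / p(a random word is
self-compatible), and *weight* = log p(two words match | the first is
self-compatible) / log p(two letters are equal), normalized so the weight
of an exact-match seed equals its length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alphabet import DNA, Alphabet

__all__ = [
    "PositionClass",
    "SeedPattern",
    "parse_pattern",
    "pattern_match",
    "self_compatible",
    "pattern_sparsity",
    "pattern_weight",
]

_DNA_LETTERS = ("a", "c", "g", "t")
_TRANSITIONS = (("a", "g"), ("g", "a"), ("c", "t"), ("t", "c"))


@dataclass(frozen=True)
class PositionClass:
    """One seed position: allowed letters and a symmetric match relation.

    The relation must be reflexive on the allowed letters and is validated
    to be a partial equivalence (symmetric + transitive), which guarantees
    letters partition into match classes — the property key-indexed hit
    counting relies on.
    """

    symbol: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for x, y in self.pairs:
            if (y, x) not in self.pairs:
                raise ValueError(f"relation for {self.symbol!r} is not symmetric")
            if (x, x) not in self.pairs or (y, y) not in self.pairs:
                raise ValueError(f"relation for {self.symbol!r} is not reflexive on allowed letters")
        for x, y in self.pairs:
            for y2, z in self.pairs:
                if y2 == y and (x, z) not in self.pairs:
                    raise ValueError(f"relation for {self.symbol!r} is not transitive")

    @property
    def allowed(self) -> frozenset[str]:
        return frozenset(x for x, y in self.pairs if x == y)

    def match_classes(self) -> dict[str, int]:
        """Map each allowed letter to its equivalence-class id."""
        reps: list[str] = []
        out: dict[str, int] = {}
        for letter in sorted(self.allowed):
            for cid, rep in enumerate(reps):
                if (letter, rep) in self.pairs:
                    out[letter] = cid
                    break
            else:
                out[letter] = len(reps)
                reps.append(letter)
        return out


def _identity(letters: tuple[str, ...]) -> frozenset[tuple[str, str]]:
    return frozenset((x, x) for x in letters)


def _complete(letters: tuple[str, ...]) -> frozenset[tuple[str, str]]:
    return frozenset((x, y) for x in letters for y in letters)


_SYMBOL_CLASSES: dict[str, PositionClass] = {
    **{
        sym: PositionClass(sym, _identity((sym.lower(),)))
        for sym in ("A", "C", "G", "T")
    },
    "N": PositionClass("N", _identity(_DNA_LETTERS)),
    "n": PositionClass("n", _complete(_DNA_LETTERS)),
    "R": PositionClass("R", _identity(("a", "g"))),
    "r": PositionClass("r", _complete(("a", "g"))),
    "Y": PositionClass("Y", _identity(("c", "t"))),
    "y": PositionClass("y", _complete(("c", "t"))),
    "@": PositionClass("@", _identity(_DNA_LETTERS) | frozenset(_TRANSITIONS)),
}


@dataclass(frozen=True)
class SeedPattern:
    """An ordered sequence of position classes."""

    classes: tuple[PositionClass, ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("a seed pattern needs at least one position")

    @property
    def length(self) -> int:
        return len(self.classes)

    @property
    def text(self) -> str:
        return "".join(c.symbol for c in self.classes)

    def __len__(self) -> int:
        return len(self.classes)


def parse_pattern(text: str) -> SeedPattern:
    """Parse a pattern string such as ``"RYN@@@nnNN@@@NN"``."""
    if not text:
        raise ValueError("empty pattern")
    classes = []
    for i, sym in enumerate(text):
        try:
            classes.append(_SYMBOL_CLASSES[sym])
        except KeyError:
            raise ValueError(f"unknown pattern symbol {sym!r} at position {i}") from None
    return SeedPattern(tuple(classes))


def pattern_match(pattern: SeedPattern, x: str, y: str) -> bool:
    """True iff words *x* and *y* match position-wise under the pattern."""
    if len(x) != pattern.length or len(y) != pattern.length:
        raise ValueError(
            f"words of length {len(x)}, {len(y)} do not fit pattern of length {pattern.length}"
        )
    return all(
        (a, b) in cls.pairs for cls, a, b in zip(pattern.classes, x.lower(), y.lower())
    )


def self_compatible(pattern: SeedPattern, x: str) -> bool:
    """True iff the pattern can start at a position holding word *x*.

    This is the position-selection predicate: a pattern whose first
    positions are R, Y selects exactly the positions of ry words.
    """
    return pattern_match(pattern, x, x)


def _position_probs(cls: PositionClass, alphabet: Alphabet) -> tuple[float, float]:
    """(p_self, p_match) for one position under the alphabet distribution."""
    prob = dict(zip(alphabet.letters, alphabet.probs))
    p_self = sum(prob[x] for x in cls.allowed if x in prob)
    p_match = sum(prob.get(x, 0.0) * prob.get(y, 0.0) for x, y in cls.pairs)
    return p_self, p_match


def pattern_sparsity(pattern: SeedPattern, alphabet: Alphabet = DNA) -> float:
    """Reciprocal of the probability that a random word is self-compatible."""
    p = 1.0
    for cls in pattern.classes:
        p_self, _ = _position_probs(cls, alphabet)
        if p_self <= 0.0:
            raise ValueError(
                f"position {cls.symbol!r} allows no letter of this alphabet: infinite sparsity"
            )
        p *= p_self
    return 1.0 / p


def pattern_weight(pattern: SeedPattern, alphabet: Alphabet = DNA) -> float:
    """log p(match | self-compatible) / log p(two random letters are equal).

    A match implies self-compatibility, so the conditional factorizes
    per position as p_match / p_self.  The denominator (1/4 for uniform
    DNA) makes an all-N exact-match pattern weigh exactly its length.
    """
    log_cond = 0.0
    for cls in pattern.classes:
        p_self, p_match = _position_probs(cls, alphabet)
        if p_self <= 0.0 or p_match <= 0.0:
            raise ValueError(f"degenerate position {cls.symbol!r}: zero match probability")
        log_cond += math.log(p_match / p_self)
    p_eq = sum(p * p for p in alphabet.probs)
    return log_cond / math.log(p_eq)
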