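"""Alphabets with per-letter probabilities.

An :class:`Alphabet` is an ordered set of single-character letters together
with an i.i.d. background distribution.  Two alphabets cover almost all use
cases: the DNA alphabet ``acgt`` parameterized by G+C content, and the binary
purine/pyrimidine alphabet ``ry`` used for word-set design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["Alphabet", "dna", "ry", "DNA", "RY", "CLASS_LETTERS"]

#: Expansion classes for degenerate word symbols (IUPAC-style subset codes).
CLASS_LETTERS: dict[str, str] = {
    "a": "a",
    "c": "c",
    "g": "g",
    "t": "t",
    "r": "ag",
    "y": "ct",
    "b": "cgt",
    "v": "acg",
    "n": "acgt",
}

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class Alphabet:
    """An ordered alphabet with an i.i.d. letter distribution.

    Parameters
    ----------
    letters:
        Distinct single-character symbols, in a fixed order.
    probs:
        Per-letter probabilities; must sum to 1 within ``1e-12``.
    """

    letters: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.letters) < 2:
            raise ValueError("an alphabet needs at least 2 letters")
        if len(set(self.letters)) != len(self.letters):
            raise ValueError("alphabet letters must be distinct")
        if any(len(c) != 1 for c in self.letters):
            raise ValueError("alphabet letters must be single characters")
        if len(self.probs) != len(self.letters):
            raise ValueError("probs and letters must have equal length")
        if any(p < 0.0 or p > 1.0 for p in self.probs):
            raise ValueError("letter probabilities must lie in [0, 1]")
        if not math.isclose(sum(self.probs), 1.0, abs_tol=_PROB_TOL):
            raise ValueError("letter probabilities must sum to 1")

    @property
    def size(self) -> int:
        return len(self.letters)

    def index(self, letter: str) -> int:
        try:
            return self.letters.index(letter)
        except ValueError:
            raise ValueError(f"letter {letter!r} is not in alphabet {self.letters}") from None

    def prob(self, letter: str) -> float:
        return self.probs[self.index(letter)]

    def is_uniform(self) -> bool:
        return all(math.isclose(p, 1.0 / self.size, abs_tol=_PROB_TOL) for p in self.probs)

    def __contains__(self, letter: str) -> bool:
        return letter in self.letters


def dna(gc: float = 0.5) -> Alphabet:
    """DNA alphabet ``(a, c, g, t)`` at stationary G+C fraction *gc*."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc content must be in (0, 1)")
    at = (1.0 - gc) / 2.0
    cg = gc / 2.0
    return Alphabet(("a", "c", "g", "t"), (at, cg, cg, at))


def ry(purine: float = 0.5) -> Alphabet:
    """Binary purine/pyrimidine alphabet ``(r, y)``."""
    if not 0.0 < purine < 1.0:
        raise ValueError("purine probability must be in (0, 1)")
    return Alphabet(("r", "y"), (purine, 1.0 - purine))


#: Uniform DNA alphabet.
DNA = dna()
#: Uniform binary ry alphabet.
RY = ry()
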