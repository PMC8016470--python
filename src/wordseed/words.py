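"""Words, word sets, overlap predicates and non-overlapping-set construction.

A word set is a set of equal-length words over an alphabet.  Two words *V*
and *W* overlap by *m* letters when the length-*m* suffix of *V* equals the
length-*m* prefix of *W*.  A set is *non-overlapping* when no proper prefix
of any word equals a proper suffix of any word (including each word against
itself).  Such sets occur anti-clumped in random sequence, which is what
makes them good sparse-seeding anchors.

All sequence and word coordinates in this package are 0-based, half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .alphabet import CLASS_LETTERS, DNA, RY, Alphabet

__all__ = [
    "WordSet",
    "overlap_indicator",
    "prefix_prob",
    "word_prob",
    "total_prob",
    "is_non_overlapping_set",
    "construct_blackburn",
    "max_non_overlapping",
    "expand_class_word",
    "all_words",
]

#: Guard on exhaustive enumeration (a**k) for the maximum-set search.
MAX_ENUMERATION = 65536

#: Degenerate-symbol classes usable over the binary ry alphabet.
_RY_CLASSES = {"r": "r", "y": "y", "n": "ry"}


@dataclass(frozen=True)
class WordSet:
    """A nonempty set of distinct, equal-length words over an alphabet.

    Words are canonicalized to lower case and stored sorted, so two word
    sets with the same members compare equal.
    """

    words: tuple[str, ...]
    alphabet: Alphabet = field(default=DNA)

    def __post_init__(self) -> None:
        canon = tuple(sorted(w.lower() for w in self.words))
        object.__setattr__(self, "words", canon)
        if not canon:
            raise ValueError("a word set must be nonempty")
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate words in word set")
        k = len(canon[0])
        if k < 1 or any(len(w) != k for w in canon):
            raise ValueError("all words must have equal length >= 1")
        for w in canon:
            for c in w:
                if c not in self.alphabet:
                    raise ValueError(f"letter {c!r} of word {w!r} is not in the alphabet")

    @property
    def k(self) -> int:
        """Common word length."""
        return len(self.words[0])

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)


def overlap_indicator(v: str, w: str, m: int) -> int:
    """1 if the length-*m* suffix of *v* equals the length-*m* prefix of *w*.

    ``m = 0`` returns 1 (the empty string trivially matches).
    """
    if m < 0 or m > len(v) or m > len(w):
        raise ValueError(f"overlap length m={m} out of range for words of length {len(v)}, {len(w)}")
    if m == 0:
        return 1
    return 1 if v[len(v) - m :] == w[:m] else 0


def prefix_prob(word: str, n: int, alphabet: Alphabet) -> float:
    """Probability of the first *n* letters of *word* under the alphabet's
    i.i.d. distribution.  ``n = 0`` gives 1 (empty product)."""
    if n < 0 or n > len(word):
        raise ValueError(f"prefix length n={n} out of range for word of length {len(word)}")
    p = 1.0
    for c in word[:n]:
        p *= alphabet.prob(c)
    return p


def word_prob(word: str, alphabet: Alphabet) -> float:
    """Probability of the full word."""
    return prefix_prob(word, len(word), alphabet)


def total_prob(ws: WordSet) -> float:
    """Total probability p that some word of the set starts at a given position."""
    return sum(word_prob(w, ws.alphabet) for w in ws.words)


def is_non_overlapping_set(ws: WordSet) -> bool:
    """True iff no proper suffix of any word equals a proper prefix of any
    word, over all ordered pairs including each word against itself."""
    k = ws.k
    for v, w in itertools.product(ws.words, repeat=2):
        for m in range(1, k):
            if overlap_indicator(v, w, m):
                return False
    return True


def _has_self_overlap(word: str) -> bool:
    return any(overlap_indicator(word, word, m) for m in range(1, len(word)))


def all_words(alphabet: Alphabet, k: int) -> list[str]:
    """All length-*k* words over the alphabet, in lexicographic letter order."""
    return ["".join(t) for t in itertools.product(alphabet.letters, repeat=k)]


def construct_blackburn(
    alphabet: Alphabet, first_subset: set[str] | str, j: int, k: int
) -> WordSet:
    """Non-overlapping words built from a two-way split of the alphabet.

    With the alphabet divided into a first subset S1 and its complement S2,
    and a prefix length *j* with ``0 < j < k``, the construction keeps the
    words whose first *j* letters are from S1, whose (j+1)-th and k-th
    letters are from S2, and whose letters from position j+1 to k contain
    no run of *j* or more S1 letters.  For DNA with S1 = {a} and j = 1 this
    yields the ``abb...b`` family (b = any base except a).
    """
    s1 = frozenset(first_subset)
    if not s1 or not s1 < set(alphabet.letters):
        raise ValueError("first_subset must be a nonempty proper subset of the alphabet")
    if not 0 < j < k:
        raise ValueError(f"need 0 < j < k, got j={j}, k={k}")
    s2 = [c for c in alphabet.letters if c not in s1]
    prefixes = itertools.product(sorted(s1), repeat=j)
    words = []
    for pre in prefixes:
        for tail in itertools.product(alphabet.letters, repeat=k - j):
            if tail[0] not in s2 or tail[-1] not in s2:
                continue
            # no run of >= j letters from S1 within positions j..k-1
            run = 0
            ok = True
            for c in tail:
                run = run + 1 if c in s1 else 0
                if run >= j:
                    ok = False
                    break
            if ok:
                words.append("".join(pre) + "".join(tail))
    return WordSet(tuple(words), alphabet)


def _compatibility_graph(words: list[str]) -> nx.Graph:
    """Graph whose vertices are self-overlap-free words, with an edge between
    two words that cannot overlap in either direction."""
    k = len(words[0])
    verts = [w for w in words if not _has_self_overlap(w)]
    graph = nx.Graph()
    graph.add_nodes_from(verts)
    for v, w in itertools.combinations(verts, 2):
        if all(
            not overlap_indicator(v, w, m) and not overlap_indicator(w, v, m)
            for m in range(1, k)
        ):
            graph.add_edge(v, w)
    return graph


def max_non_overlapping(
    k: int, alphabet: Alphabet = DNA, max_enumeration: int = MAX_ENUMERATION
) -> WordSet:
    """A maximum set of pairwise non-overlapping length-*k* words.

    Builds the word-compatibility graph (self-overlapping words are excluded
    up front; an edge joins two words that cannot overlap either way) and
    solves maximum clique exactly.  The search is exhaustive, so ``a**k`` is
    capacity-guarded; note that solve time grows steeply with *k* even below
    the guard (DNA k=5 takes a few seconds, k=6 much longer).
    """
    if k < 2:
        raise ValueError("word length k must be >= 2")
    n_words = alphabet.size**k
    if n_words > max_enumeration:
        raise ValueError(
            f"{alphabet.size}**{k} = {n_words} words exceeds the enumeration guard "
            f"({max_enumeration}); raise max_enumeration to force the search"
        )
    graph = _compatibility_graph(all_words(alphabet, k))
    clique, _ = nx.max_weight_clique(graph, weight=None)
    return WordSet(tuple(clique), alphabet)


def expand_class_word(word: str, alphabet: Alphabet = DNA) -> WordSet:
    """Expand a word with degenerate class symbols into a concrete word set.

    Over DNA the symbols ``r`` (a/g), ``y`` (c/t), ``b`` (not a), ``v``
    (not t) and ``n`` (any) are recognized alongside literal ``acgt``; over
    the binary ry alphabet, ``r``, ``y`` and ``n`` are recognized.  The
    result has one word per combination of class members.
    """
    word = word.lower()
    letters = set(alphabet.letters)
    if letters == {"a", "c", "g", "t"}:
        classes = CLASS_LETTERS
    elif letters == {"r", "y"}:
        classes = _RY_CLASSES
    else:
        raise ValueError("class-symbol expansion is defined for the DNA and ry alphabets only")
    choices = []
    for i, c in enumerate(word):
        if c not in classes:
            raise ValueError(f"unknown class symbol {c!r} at position {i} of {word!r}")
        choices.append(classes[c])
    return WordSet(tuple("".join(t) for t in itertools.product(*choices)), alphabet)
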