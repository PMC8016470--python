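"""Seeding schemes: every-nth, word-restricted and minimizer position selection.

A scheme maps a DNA sequence to the set of 0-based positions at which seeds
are allowed to start.  Three families are provided:

* every-nth — positions 0, n, 2n, ...; applied to one of the two sequences
  being compared;
* word-restricted — positions where one of a designed set of words occurs;
  applied to both sequences;
* minimizers — positions that are minimal, under a chosen ordering, in some
  window of *w* consecutive positions; applied to both sequences.

Minimizer orderings compare the suffixes starting at each position using
per-depth letter ranks, truncated at a fixed comparison horizon; positions
whose truncated suffixes compare equal fall back to position index (the
smaller index ranks first).  A hash ordering on fixed-length k-mers is also
provided for minimap-style schemes; its expected density on random
sequence is 2/(w+1).

Sequences are handled as numpy uint8 code arrays (a,c,g,t -> 0..3; any
other letter -> 4).  Letters outside acgt rank above all real letters in
every ordering and never begin a selected word.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .alphabet import CLASS_LETTERS
from .patterns import SeedPattern
from .words import WordSet

__all__ = [
    "encode",
    "decode",
    "SuffixOrdering",
    "HashOrdering",
    "make_ordering",
    "compare_suffixes",
    "minimizer_positions",
    "select_every_nth",
    "select_word_positions",
    "select_pattern_positions",
    "word_kmer_codes",
    "density",
    "sparsity",
    "EveryNth",
    "WordRestricted",
    "PatternRestricted",
    "MinimizerSelect",
    "SeedingScheme",
]

_CODE = {"a": 0, "c": 1, "g": 2, "t": 3}
_AMBIG = 4  # non-acgt letters
_PAST_END = 5  # virtual rank past the sequence end
#: Suffix comparisons look at most this many letters deep; 6**24 < 2**63,
#: so a whole truncated suffix packs into one unsigned 64-bit key.
HORIZON = 24
_BASE = 6

# per-depth rank tables, indexed by letter code 0..5
_ALPHABETIC = np.array([0, 1, 2, 3, _AMBIG, _PAST_END], dtype=np.uint64)
# odd depths (1-based; 0-based even): c < a < t < g
_CG_ODD = np.array([1, 0, 3, 2, _AMBIG, _PAST_END], dtype=np.uint64)
# even depths (1-based; 0-based odd): g < t < a < c
_CG_EVEN = np.array([2, 3, 0, 1, _AMBIG, _PAST_END], dtype=np.uint64)
# abb order: a < c < g < t at depth 1, then t = g = c < a
_ABB_FIRST = _ALPHABETIC
_ABB_REST = np.array([1, 0, 0, 0, _AMBIG, _PAST_END], dtype=np.uint64)


def encode(seq: str) -> np.ndarray:
    """Sequence string to uint8 codes (case-insensitive; non-acgt -> 4)."""
    out = np.full(len(seq), _AMBIG, dtype=np.uint8)
    arr = np.frombuffer(seq.lower().encode("ascii"), dtype=np.uint8)
    for letter, code in _CODE.items():
        out[arr == ord(letter)] = code
    return out


def decode(codes: np.ndarray) -> str:
    return "".join("acgtn"[min(c, 4)] for c in codes)


@dataclass(frozen=True)
class SuffixOrdering:
    """A total preorder on sequence positions via per-depth letter ranks.

    kind: 'alphabetic', 'cg' (cgcg... is the minimum sequence) or 'abb'
    (a first, then all non-a letters tie below a).
    """

    kind: str = "alphabetic"
    horizon: int = HORIZON

    def __post_init__(self) -> None:
        if self.kind not in ("alphabetic", "cg", "abb"):
            raise ValueError(f"unknown suffix ordering {self.kind!r}")
        if not 1 <= self.horizon <= HORIZON:
            raise ValueError(f"horizon must be in 1..{HORIZON}")

    def rank_table(self, depth: int) -> np.ndarray:
        """Letter ranks at 0-based comparison depth."""
        if self.kind == "alphabetic":
            return _ALPHABETIC
        if self.kind == "cg":
            return _CG_ODD if depth % 2 == 0 else _CG_EVEN
        return _ABB_FIRST if depth == 0 else _ABB_REST

    def num_candidates(self, seq_len: int) -> int:
        return seq_len

    def keys(self, codes: np.ndarray) -> np.ndarray:
        """Packed base-6 suffix keys; works on 1-D or 2-D code arrays.

        Smaller key = smaller suffix.  Positions past the end contribute a
        rank above every letter, so a short suffix that matches a longer
        one letter-for-letter compares larger and the tie-break stays with
        the position index (leftmost argmin).
        """
        codes = np.asarray(codes, dtype=np.uint8)
        n = codes.shape[-1]
        padded = np.concatenate(
            [codes, np.full(codes.shape[:-1] + (self.horizon,), _PAST_END, dtype=np.uint8)],
            axis=-1,
        )
        keys = np.zeros(codes.shape, dtype=np.uint64)
        for depth in range(self.horizon):
            keys *= np.uint64(_BASE)
            keys += self.rank_table(depth)[padded[..., depth : depth + n]]
        return keys


_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = (x + _GOLDEN).astype(np.uint64)
    x ^= x >> np.uint64(30)
    x *= _MIX1
    x ^= x >> np.uint64(27)
    x *= _MIX2
    x ^= x >> np.uint64(31)
    return x


@dataclass(frozen=True)
class HashOrdering:
    """Pseudo-random ordering of positions by a 64-bit hash of the k-mer
    starting there.  K-mers containing non-acgt letters rank last; equal
    k-mers (hence equal hashes) fall back to position index."""

    k: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 31:
            raise ValueError("k-mer length must be in 1..31")

    def num_candidates(self, seq_len: int) -> int:
        return max(seq_len - self.k + 1, 0)

    def keys(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=np.uint8)
        n = codes.shape[-1]
        if n < self.k:
            return np.zeros(codes.shape[:-1] + (0,), dtype=np.uint64)
        npos = n - self.k + 1
        vals = np.zeros(codes.shape[:-1] + (npos,), dtype=np.uint64)
        bad = np.zeros(codes.shape[:-1] + (npos,), dtype=bool)
        with np.errstate(over="ignore"):
            for d in range(self.k):
                window = codes[..., d : d + npos]
                vals = (vals << np.uint64(2)) | (window & np.uint8(3)).astype(np.uint64)
                bad |= window >= _AMBIG
            keys = _splitmix64(vals ^ np.uint64(self.seed & (2**64 - 1)))
        keys[bad] = np.iinfo(np.uint64).max
        return keys


Ordering = SuffixOrdering | HashOrdering


def make_ordering(kind: str, **kwargs) -> Ordering:
    """Factory: 'alphabetic' | 'cg' | 'abb' | 'hash'."""
    if kind == "hash":
        return HashOrdering(**kwargs)
    return SuffixOrdering(kind=kind, **kwargs)


def compare_suffixes(seq: str | np.ndarray, i: int, j: int, ordering: Ordering) -> int:
    """-1/0/+1 comparison of the suffixes starting at *i* and *j*.

    Letter-by-letter scalar comparison, truncated at the ordering's
    horizon; 0 means the comparison was exhausted or tied, in which case
    the caller breaks the tie by position index.  This is the reference
    semantics the packed-key implementation must agree with.
    """
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    n = len(codes)
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError("positions out of range")
    if isinstance(ordering, HashOrdering):
        keys = ordering.keys(codes)
        if i >= len(keys) or j >= len(keys):
            raise ValueError("position has no full k-mer under a hash ordering")
        return int(keys[i] > keys[j]) - int(keys[i] < keys[j])
    for depth in range(ordering.horizon):
        table = ordering.rank_table(depth)
        ri = table[codes[i + depth]] if i + depth < n else _PAST_END
        rj = table[codes[j + depth]] if j + depth < n else _PAST_END
        if ri != rj:
            return -1 if ri < rj else 1
        if ri == _PAST_END:  # both exhausted
            return 0
    return 0


def _window_argmin(keys: np.ndarray, w: int, chunk: int = 1 << 18) -> np.ndarray:
    """Leftmost argmin of every length-w window along the last axis (1-D)."""
    n = keys.shape[0]
    n_win = n - w + 1
    out = np.empty(n_win, dtype=np.int64)
    for start in range(0, n_win, chunk):
        stop = min(start + chunk, n_win)
        view = np.lib.stride_tricks.sliding_window_view(keys[start : stop + w - 1], w)
        out[start:stop] = view.argmin(axis=1) + np.arange(start, stop)
    return out


def minimizer_positions(
    seq: str | np.ndarray,
    w: int,
    ordering: Ordering,
    include_end_windows: bool = False,
) -> np.ndarray:
    """Positions minimal in at least one window of *w* consecutive positions.

    Windows slide over the ordering's candidate positions (all positions
    for suffix orderings; positions with a full k-mer for hash orderings)
    and must fit inside the sequence unless `include_end_windows` is set,
    in which case the truncated windows at the right edge are also taken.
    Ties within a window go to the leftmost position.
    """
    if w < 1:
        raise ValueError("window length w must be >= 1")
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    keys = ordering.keys(codes)
    n_cand = keys.shape[0]
    if n_cand == 0 or n_cand < w and not include_end_windows:
        raise ValueError(f"sequence has {n_cand} candidate positions, fewer than w={w}")
    picks = _window_argmin(keys, min(w, n_cand))
    if include_end_windows:
        tail = [int(keys[s:].argmin()) + s for s in range(max(n_cand - w + 1, 1), n_cand)]
        picks = np.concatenate([picks, np.array(tail, dtype=np.int64)])
    return np.unique(picks)


def select_every_nth(seq_len: int, n: int) -> np.ndarray:
    """Positions 0, n, 2n, ... below seq_len."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.arange(0, seq_len, n, dtype=np.int64)


def word_kmer_codes(ws: WordSet | tuple[str, ...]) -> tuple[int, np.ndarray]:
    """(k, sorted base-4 codes) of the DNA words of a word set.

    Word sets over the binary ry alphabet (or plain tuples of degenerate
    class words such as ``("rrry", ...)``) are expanded to DNA first.
    """
    if isinstance(ws, WordSet):
        letters = set(ws.alphabet.letters)
        words = ws.words if letters == {"a", "c", "g", "t"} else None
        texts = ws.words
    else:
        words, texts = None, tuple(ws)
    if words is None:
        expanded: set[str] = set()
        for text in texts:
            if any(c not in CLASS_LETTERS for c in text.lower()):
                raise ValueError(f"cannot expand word {text!r} to DNA")
            choices = [CLASS_LETTERS[c] for c in text.lower()]
            expanded.update("".join(t) for t in itertools.product(*choices))
        words = tuple(sorted(expanded))
    k = len(words[0])
    if any(len(w) != k for w in words):
        raise ValueError("all words must have equal length")
    codes = np.array(
        [sum(_CODE[c] << (2 * (k - 1 - d)) for d, c in enumerate(w)) for w in words],
        dtype=np.int64,
    )
    return k, np.unique(codes)


def _rolling_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 k-mer codes along the last axis, plus a validity mask."""
    n = codes.shape[-1]
    npos = n - k + 1
    if npos <= 0:
        shape = codes.shape[:-1] + (0,)
        return np.zeros(shape, np.int64), np.zeros(shape, bool)
    vals = np.zeros(codes.shape[:-1] + (npos,), dtype=np.int64)
    ok = np.ones(codes.shape[:-1] + (npos,), dtype=bool)
    for d in range(k):
        window = codes[..., d : d + npos]
        vals = (vals << 2) | (window & 3).astype(np.int64)
        ok &= window < _AMBIG
    return vals, ok


def select_word_positions(seq: str | np.ndarray, ws: WordSet | tuple[str, ...]) -> np.ndarray:
    """All positions where some word of the set occurs."""
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    k, word_codes = word_kmer_codes(ws)
    if len(codes) < k:
        raise ValueError(f"sequence of length {len(codes)} is shorter than word length {k}")
    vals, ok = _rolling_codes(codes, k)
    return np.flatnonzero(np.isin(vals, word_codes) & ok)


def select_pattern_positions(seq: str | np.ndarray, pattern: SeedPattern) -> np.ndarray:
    """Positions at which a random seed under the pattern could start:
    those whose next ``len(pattern)`` letters are all self-compatible."""
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    length = pattern.length
    npos = len(codes) - length + 1
    if npos <= 0:
        raise ValueError("sequence shorter than the pattern")
    ok = np.ones(npos, dtype=bool)
    for d, cls in enumerate(pattern.classes):
        allowed = np.zeros(6, dtype=bool)
        for letter in cls.allowed:
            allowed[_CODE[letter]] = True
        ok &= allowed[codes[d : d + npos]]
    return np.flatnonzero(ok)


@dataclass(frozen=True)
class EveryNth:
    """Seeds start at every n-th position of ONE of the two sequences.

    Restricting both sequences to the same stride would miss any homology
    whose coordinates differ by less than the stride, so this scheme is
    one-sided by construction.
    """

    n: int
    both_sequences = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def describe(self) -> str:
        return f"every-{self.n}th"

    def positions(self, codes: np.ndarray) -> np.ndarray:
        return select_every_nth(len(codes), self.n)

    def selection_mask(self, codes2d: np.ndarray) -> np.ndarray:
        n_rows, length = codes2d.shape
        cols = np.arange(length) % self.n == 0
        return np.broadcast_to(cols, (n_rows, length))


@dataclass(frozen=True)
class WordRestricted:
    """Seeds start at positions of any word from a designed set, in both
    sequences.  Words may be concrete DNA words or degenerate class words
    (e.g. ``("rrry", "ryrr", "ryyr", "yyyr")``)."""

    words: tuple[str, ...]
    both_sequences = True

    def describe(self) -> str:
        label = ",".join(self.words[:4]) + ("..." if len(self.words) > 4 else "")
        return f"words({label})"

    def _codes(self) -> tuple[int, np.ndarray]:
        return word_kmer_codes(self.words)

    def positions(self, codes: np.ndarray) -> np.ndarray:
        return select_word_positions(codes, self.words)

    def selection_mask(self, codes2d: np.ndarray) -> np.ndarray:
        k, word_codes = self._codes()
        n_rows, length = codes2d.shape
        vals, ok = _rolling_codes(codes2d, k)
        mask = np.zeros((n_rows, length), dtype=bool)
        mask[:, : length - k + 1] = np.isin(vals, word_codes) & ok
        return mask


@dataclass(frozen=True)
class PatternRestricted:
    """Seeds start at positions self-compatible with a subset-seed pattern,
    in both sequences.  With a pattern whose restricted prefix encodes a
    word set (e.g. leading R, Y), this coincides with word restriction."""

    pattern: SeedPattern
    both_sequences = True

    def describe(self) -> str:
        return f"pattern({self.pattern.text})"

    def positions(self, codes: np.ndarray) -> np.ndarray:
        return select_pattern_positions(codes, self.pattern)

    def selection_mask(self, codes2d: np.ndarray) -> np.ndarray:
        n_rows, length = codes2d.shape
        span = self.pattern.length
        npos = length - span + 1
        mask = np.zeros((n_rows, length), dtype=bool)
        ok = np.ones((n_rows, npos), dtype=bool)
        for d, cls in enumerate(self.pattern.classes):
            allowed = np.zeros(6, dtype=bool)
            for letter in cls.allowed:
                allowed[_CODE[letter]] = True
            ok &= allowed[codes2d[:, d : d + npos]]
        mask[:, :npos] = ok
        return mask


@dataclass(frozen=True)
class MinimizerSelect:
    """Seeds start at minimizer positions (window *w*, given ordering), in
    both sequences."""

    ordering: Ordering
    w: int
    both_sequences = True

    def describe(self) -> str:
        kind = getattr(self.ordering, "kind", "hash")
        return f"minimizer({kind},w={self.w})"

    def positions(self, codes: np.ndarray) -> np.ndarray:
        return minimizer_positions(codes, self.w, self.ordering)

    def selection_mask(self, codes2d: np.ndarray) -> np.ndarray:
        n_rows, length = codes2d.shape
        keys = self.ordering.keys(codes2d)
        n_cand = keys.shape[1]
        if n_cand < self.w:
            raise ValueError(f"{n_cand} candidate positions, fewer than w={self.w}")
        windows = np.lib.stride_tricks.sliding_window_view(keys, self.w, axis=1)
        picks = windows.argmin(axis=2) + np.arange(n_cand - self.w + 1)
        mask = np.zeros((n_rows, length), dtype=bool)
        mask[np.arange(n_rows)[:, None], picks] = True
        return mask


SeedingScheme = EveryNth | WordRestricted | PatternRestricted | MinimizerSelect


def density(positions: np.ndarray, usable: int) -> float:
    """Fraction of usable positions selected."""
    if usable <= 0:
        raise ValueError("usable position count must be positive")
    return len(positions) / usable


def sparsity(positions: np.ndarray, usable: int) -> float:
    """Average distance between selected positions (1/density)."""
    d = density(positions, usable)
    return float("inf") if d == 0.0 else 1.0 / d
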