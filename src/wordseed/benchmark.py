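"""Seeding sensitivity and specificity benchmark.

The experimental design: simulate pairs of sequences related by the T92
substitution process (default: G+C 50%, κ=1, PAM 20, length 100) and call
a pair *found* when the scheme selects some coordinate — in one sequence
for every-nth schemes, in both sequences for word-restricted and minimizer
schemes — at which the seed matches at the same 0-based coordinate of both
sequences (exact substring equality for exact-match seeds, pattern matching
for subset seeds).  *Sensitivity* is the fraction of pairs found.
*Specificity* is proxied by the number of seed matches between two
unrelated random sequences (default length 10^6), counted by grouping
selected positions on their seed key rather than by all-pairs enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evolution import T92Params, SequencePair, mutate_codes, simulate_pair_codes
from .patterns import SeedPattern
from .schemes import SeedingScheme, _CODE, _rolling_codes, encode

__all__ = [
    "SeedSpec",
    "BenchResult",
    "pair_found",
    "sensitivity",
    "specificity",
    "conserved_seed_count",
    "pareto_sweep",
]

_BATCH = 4096


@dataclass(frozen=True)
class SeedSpec:
    """An exact-match seed of a given length, or a subset-seed pattern."""

    length: int | None = None
    pattern: SeedPattern | None = None

    def __post_init__(self) -> None:
        if (self.length is None) == (self.pattern is None):
            raise ValueError("specify exactly one of length (exact seed) or pattern")
        if self.length is not None and self.length < 1:
            raise ValueError("seed length must be >= 1")

    @classmethod
    def exact(cls, length: int) -> "SeedSpec":
        return cls(length=length)

    @classmethod
    def subset(cls, pattern: SeedPattern) -> "SeedSpec":
        return cls(pattern=pattern)

    @property
    def span(self) -> int:
        return self.length if self.length is not None else self.pattern.length

    def describe(self) -> str:
        return f"exact{self.length}" if self.length is not None else self.pattern.text


@dataclass(frozen=True)
class BenchResult:
    """One benchmark measurement."""

    scheme: str
    seed_spec: str
    sensitivity: float | None
    random_hits: int | None
    n: int
    seq_len: int
    seed: int | None


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def _pair_tables(spec: SeedSpec) -> np.ndarray | None:
    """Per-depth 6x6 letter-pair match tables for a pattern seed."""
    if spec.pattern is None:
        return None
    tables = np.zeros((spec.pattern.length, 6, 6), dtype=bool)
    for d, cls in enumerate(spec.pattern.classes):
        for x, y in cls.pairs:
            tables[d, _CODE[x], _CODE[y]] = True
    return tables


def _conserved_mask(a: np.ndarray, b: np.ndarray, spec: SeedSpec) -> np.ndarray:
    """Coordinates where the seed matches between paired rows of a and b."""
    n_rows, length = a.shape
    span = spec.span
    npos = length - span + 1
    if npos <= 0:
        raise ValueError(f"seed span {span} exceeds sequence length {length}")
    if spec.length is not None:
        site = (a == b) & (a < 4)
        ok = np.ones((n_rows, npos), dtype=bool)
        for d in range(span):
            ok &= site[:, d : d + npos]
        return ok
    tables = _pair_tables(spec)
    ok = np.ones((n_rows, npos), dtype=bool)
    for d in range(span):
        ok &= tables[d][a[:, d : d + npos], b[:, d : d + npos]]
    return ok


def _found_rows(
    a: np.ndarray, b: np.ndarray, scheme: SeedingScheme, spec: SeedSpec
) -> np.ndarray:
    npos = a.shape[1] - spec.span + 1
    conserved = _conserved_mask(a, b, spec)
    sel = scheme.selection_mask(a)[:, :npos]
    hit = conserved & sel
    if scheme.both_sequences:
        hit &= scheme.selection_mask(b)[:, :npos]
    return hit.any(axis=1)


def pair_found(pair: SequencePair, scheme: SeedingScheme, spec: SeedSpec) -> bool:
    """True iff the scheme finds a seed match at identical coordinates."""
    a = encode(pair.seq_a)[None, :]
    b = encode(pair.seq_b)[None, :]
    return bool(_found_rows(a, b, scheme, spec)[0])


def sensitivity(
    scheme: SeedingScheme,
    spec: SeedSpec,
    n_pairs: int,
    seq_len: int = 100,
    params: T92Params = T92Params(),
    rng: np.random.Generator | int | None = None,
) -> BenchResult:
    """Fraction of simulated related pairs with >= 1 seed match at
    homologous (identical) coordinates."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    seed = rng if isinstance(rng, int) else None
    gen = _as_rng(rng)
    found = 0
    remaining = n_pairs
    while remaining > 0:
        batch = min(remaining, _BATCH)
        a, b = simulate_pair_codes(batch, seq_len, params, gen)
        found += int(_found_rows(a, b, scheme, spec).sum())
        remaining -= batch
    return BenchResult(
        scheme=scheme.describe(),
        seed_spec=spec.describe(),
        sensitivity=found / n_pairs,
        random_hits=None,
        n=n_pairs,
        seq_len=seq_len,
        seed=seed,
    )


def _seed_keys(codes: np.ndarray, positions: np.ndarray, spec: SeedSpec) -> np.ndarray:
    """Group key of the seed starting at each position (pattern seeds use
    the per-position match-class projection; incompatible positions drop)."""
    span = spec.span
    positions = positions[positions <= len(codes) - span]
    if spec.length is not None:
        vals, ok = _rolling_codes(codes, span)
        keys = vals[positions]
        return keys[ok[positions]]
    base = 4
    keys = np.zeros(len(positions), dtype=np.int64)
    ok = np.ones(len(positions), dtype=bool)
    for d, cls in enumerate(spec.pattern.classes):
        ids = np.full(6, -1, dtype=np.int64)
        for letter, cid in cls.match_classes().items():
            ids[_CODE[letter]] = cid
        here = ids[codes[positions + d]]
        ok &= here >= 0
        keys = keys * base + np.where(here >= 0, here, 0)
    return keys[ok]


def specificity(
    scheme: SeedingScheme,
    spec: SeedSpec,
    seq_len: int = 1_000_000,
    gc: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Number of seed matches between two unrelated random sequences.

    Counts ordered position pairs (i, j) with i selected in sequence 1,
    j selected in sequence 2 (all j for one-sided schemes), whose seeds
    match.  A proxy for the cost of checking seed hits.
    """
    if seq_len < spec.span:
        raise ValueError("seq_len must be at least the seed span")
    gen = _as_rng(rng)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    s1 = gen.choice(4, size=seq_len, p=probs).astype(np.uint8)
    s2 = gen.choice(4, size=seq_len, p=probs).astype(np.uint8)
    pos1 = scheme.positions(s1)
    pos2 = (
        scheme.positions(s2)
        if scheme.both_sequences
        else np.arange(seq_len, dtype=np.int64)
    )
    k1 = _seed_keys(s1, pos1, spec)
    k2 = _seed_keys(s2, pos2, spec)
    u1, c1 = np.unique(k1, return_counts=True)
    u2, c2 = np.unique(k2, return_counts=True)
    common, i1, i2 = np.intersect1d(u1, u2, assume_unique=True, return_indices=True)
    return int((c1[i1] * c2[i2]).sum())


def conserved_seed_count(
    seq: str | np.ndarray,
    params: T92Params,
    scheme: SeedingScheme,
    spec: SeedSpec,
    n_fragments: int = 1000,
    fragment_len: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Average number of conserved seeds per mutated fragment.

    Random fragments are drawn from *seq*, mutated by the T92 process, and
    the coordinates selected in BOTH the original and mutated fragment
    where the seed matches are counted.
    """
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    if len(codes) < fragment_len:
        raise ValueError("sequence shorter than fragment_len")
    gen = _as_rng(rng)
    starts = gen.integers(0, len(codes) - fragment_len + 1, size=n_fragments)
    orig = np.stack([codes[s : s + fragment_len] for s in starts])
    mut = mutate_codes(orig, params, gen)
    npos = fragment_len - spec.span + 1
    conserved = _conserved_mask(orig, mut, spec)
    sel = scheme.selection_mask(orig)[:, :npos]
    if scheme.both_sequences:
        sel = sel & scheme.selection_mask(mut)[:, :npos]
    return float((conserved & sel).sum(axis=1).mean())


def pareto_sweep(
    scheme: SeedingScheme,
    specs: list[SeedSpec],
    n_pairs: int,
    seq_len: int = 100,
    params: T92Params = T92Params(),
    specificity_len: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Sensitivity and random-hit count for each seed spec: the
    (random_hits, sensitivity) trade-off curve of a scheme."""
    gen = _as_rng(rng)
    rows = []
    for spec in specs:
        sens = sensitivity(scheme, spec, n_pairs, seq_len, params, gen)
        hits = specificity(scheme, spec, specificity_len, params.gc, gen)
        rows.append(
            {
                "scheme": scheme.describe(),
                "seed_spec": spec.describe(),
                "span": spec.span,
                "sensitivity": sens.sensitivity,
                "random_hits": hits,
                "n_pairs": n_pairs,
                "seq_len": seq_len,
            }
        )
    return pd.DataFrame(rows)
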