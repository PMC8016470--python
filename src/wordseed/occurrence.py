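"""Exact occurrence-count statistics for word sets in random i.i.d. sequences.

Let X be the number of positions of a random length-*s* sequence at which
some word of a length-*k* word set starts, and let *p* be the total word
probability per position.  The mean is ``(s-k+1)p`` for a linear sequence
and ``sp`` for a circular one.  The variance involves, in addition, the
pairwise overlap structure of the words: for every ordered pair (V, W) and
every lag ``l in 1..k-1``, an overlap term contributes when the length
``k-l`` suffix of V equals the corresponding prefix of W.

Two variance-to-mean ratios (VMR, index of dispersion) summarize clumping
independent of sequence length:

* ``vmr1`` — the circular-sequence ratio, equal to the long-sequence limit
  of the linear ratio;
* ``vmr2`` — the linear ratio at the shortest length, ``s = 2k-1``, at
  which every kind of pairwise overlap contributes.

Non-overlapping word sets have VMR < 1: they are anti-clumped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .words import WordSet, overlap_indicator, prefix_prob, total_prob, word_prob

__all__ = [
    "OccurrenceStats",
    "occurrence_mean",
    "occurrence_variance",
    "vmr1",
    "vmr2",
    "empirical_occurrence_stats",
]

Topology = Literal["linear", "circular"]


@dataclass(frozen=True)
class OccurrenceStats:
    """Mean, variance and VMR of an occurrence count."""

    mean: float
    variance: float
    vmr: float
    topology: Topology
    seq_len: int
    trials: int | None = None  # None for analytic values


def _check_topology(topology: str) -> None:
    if topology not in ("linear", "circular"):
        raise ValueError(f"topology must be 'linear' or 'circular', got {topology!r}")


def _overlap_sum(ws: WordSet, weighted: bool) -> float:
    """Sum over ordered word pairs and lags of the overlap contribution.

    Unweighted: sum of ``B(V,W,k-l) * P_V(l) * P_W(k)`` over ``l = 1..k-1``.
    Weighted: each term carries an extra factor ``k - l`` (the short-linear
    variance needs it).
    """
    k = ws.k
    alpha = ws.alphabet
    full = {w: word_prob(w, alpha) for w in ws.words}
    total = 0.0
    for v in ws.words:
        for w in ws.words:
            for lag in range(1, k):
                if overlap_indicator(v, w, k - lag):
                    term = prefix_prob(v, lag, alpha) * full[w]
                    total += (k - lag) * term if weighted else term
    return total


def occurrence_mean(ws: WordSet, s: int, topology: Topology = "linear") -> float:
    """Expected occurrence count: ``(s-k+1)p`` linear, ``sp`` circular."""
    _check_topology(topology)
    k = ws.k
    p = total_prob(ws)
    if topology == "linear":
        if s < k:
            raise ValueError(f"linear sequence length s={s} must be >= k={k}")
        return (s - k + 1) * p
    if s < 2 * k - 1:
        raise ValueError(f"circular sequence length s={s} must be >= 2k-1={2 * k - 1}")
    return s * p


def _variance_direct(ws: WordSet, s: int) -> float:
    """O(s^2) summation of E[I_i I_j] over all position pairs (linear).

    Valid for any s >= k; used as the slow fallback when s < 2k-2, where
    the closed form does not apply.
    """
    k = ws.k
    alpha = ws.alphabet
    p = total_prob(ws)
    full = {w: word_prob(w, alpha) for w in ws.words}
    npos = s - k + 1
    # E[I_i I_j] depends only on the lag l = |i - j|
    cross_by_lag = {}
    for lag in range(1, k):
        tot = 0.0
        for v in ws.words:
            for w in ws.words:
                if overlap_indicator(v, w, k - lag):
                    tot += prefix_prob(v, lag, alpha) * full[w]
        cross_by_lag[lag] = tot
    ex2 = 0.0
    for i in range(npos):
        for j in range(npos):
            lag = abs(i - j)
            if lag == 0:
                ex2 += p
            elif lag < k:
                ex2 += cross_by_lag[lag]
            else:
                ex2 += p * p
    return ex2 - (npos * p) ** 2


def occurrence_variance(ws: WordSet, s: int, topology: Topology = "linear") -> float:
    """Variance of the occurrence count.

    Linear sequences use the closed form valid for ``s >= 2k-2`` and fall
    back to direct O(s^2) summation for ``k <= s < 2k-2``; circular
    sequences require ``s >= 2k-1``.
    """
    _check_topology(topology)
    k = ws.k
    p = total_prob(ws)
    if topology == "circular":
        if s < 2 * k - 1:
            raise ValueError(f"circular sequence length s={s} must be >= 2k-1={2 * k - 1}")
        return s * (p - (2 * k - 1) * p * p + 2.0 * _overlap_sum(ws, weighted=False))
    if s < k:
        raise ValueError(f"linear sequence length s={s} must be >= k={k}")
    if s < 2 * k - 2:
        return _variance_direct(ws, s)
    k_ = float(k)
    npos = s - k + 1
    cross = 0.0
    alpha = ws.alphabet
    full = {w: word_prob(w, alpha) for w in ws.words}
    for v in ws.words:
        for w in ws.words:
            for lag in range(1, k):
                if overlap_indicator(v, w, k - lag):
                    cross += (npos - lag) * prefix_prob(v, lag, alpha) * full[w]
    return (
        npos * p
        + 2.0 * cross
        - ((2 * k_ - 1) * s - (3 * k_ - 1) * (k_ - 1)) * p * p
    )


def _safe_vmr(variance: float, mean: float) -> float:
    if mean <= 0.0:
        warnings.warn("word set has zero occurrence probability; VMR defined as 0")
        return 0.0
    return variance / mean


def vmr1(ws: WordSet) -> float:
    """Circular-sequence variance-to-mean ratio (length-independent).

    Equals ``1 - (2k-1)p + 2*S/p`` where S is the unweighted overlap sum;
    for a non-overlapping set this reduces to ``1 - (2k-1)p``.
    """
    p = total_prob(ws)
    if p <= 0.0:
        return _safe_vmr(0.0, p)
    k = ws.k
    return 1.0 - (2 * k - 1) * p + 2.0 * _overlap_sum(ws, weighted=False) / p


def vmr2(ws: WordSet) -> float:
    """Linear variance-to-mean ratio at sequence length ``s = 2k-1``.

    The shortest linear length at which every pairwise overlap lag
    contributes; the mean there is ``kp``.
    """
    p = total_prob(ws)
    if p <= 0.0:
        return _safe_vmr(0.0, p)
    k = ws.k
    kp = k * p
    variance = kp - kp * kp + 2.0 * _overlap_sum(ws, weighted=True)
    return variance / kp


def _letter_codes(ws: WordSet) -> tuple[np.ndarray, np.ndarray]:
    """Word rows as integer codes plus the alphabet's probability vector."""
    index = {c: i for i, c in enumerate(ws.alphabet.letters)}
    rows = np.array([[index[c] for c in w] for w in ws.words], dtype=np.int64)
    return rows, np.asarray(ws.alphabet.probs)


def empirical_occurrence_stats(
    ws: WordSet,
    s: int,
    topology: Topology = "linear",
    trials: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> OccurrenceStats:
    """Monte-Carlo mean/variance of the occurrence count.

    Draws `trials` i.i.d. sequences from the alphabet's letter distribution
    and counts word-set occurrences in each.  Serves as the simulation
    oracle for the analytic formulas.
    """
    _check_topology(topology)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    k = ws.k
    if topology == "linear" and s < k:
        raise ValueError(f"linear sequence length s={s} must be >= k={k}")
    if topology == "circular" and s < 2 * k - 1:
        raise ValueError(f"circular sequence length s={s} must be >= 2k-1={2 * k - 1}")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows, probs = _letter_codes(ws)
    seqs = gen.choice(len(probs), size=(trials, s), p=probs)
    if topology == "circular":
        seqs = np.concatenate([seqs, seqs[:, : k - 1]], axis=1)
    windows = np.lib.stride_tricks.sliding_window_view(seqs, k, axis=1)
    hits = np.zeros(windows.shape[:2], dtype=bool)
    for row in rows:
        hits |= (windows == row).all(axis=2)
    counts = hits.sum(axis=1)
    mean = float(counts.mean())
    if trials == 1:
        warnings.warn("single-trial variance is undefined; returning 0")
        variance = 0.0
    else:
        variance = float(counts.var(ddof=1))
    return OccurrenceStats(
        mean=mean,
        variance=variance,
        vmr=_safe_vmr(variance, mean),
        topology=topology,
        seq_len=s,
        trials=trials,
    )
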