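"""Search for word sets minimizing a variance-to-mean ratio.

At fixed word length *k* and set size *m* over an alphabet with uniform
letter probabilities, both VMR objectives are affine increasing functions
of the total pairwise overlap contribution

    T(S) = sum over ordered pairs (V, W) in S of
           sum over lags l = 1..k-1 of [l-weight] * B(V,W,k-l) * P_V(l) * P_W(k)

(the lag weight is 1 for VMR1 and k-l for VMR2), because the per-position
probability p = m * a**-k is fixed.  Minimizing the VMR therefore reduces
to minimizing a quadratic set function with nonnegative pairwise terms,
which supports exact branch-and-bound enumeration of all m-subsets (with
ties collected) and, beyond exhaustive reach, simulated annealing over
single-word swaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Literal

import numpy as np
from numba import njit

from .alphabet import RY, Alphabet
from .occurrence import vmr1, vmr2
from .words import WordSet, all_words, overlap_indicator, prefix_prob, word_prob

__all__ = [
    "SearchConfig",
    "SearchResult",
    "score_wordset",
    "exhaustive_min_vmr",
    "anneal_min_vmr",
]

Objective = Literal["vmr1", "vmr2"]

#: Cap on candidate evaluations for the exhaustive search.
MAX_EVALUATIONS = 10**8
#: Maximum number of tied optima retained.
MAX_TIES = 512
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class SearchConfig:
    """Configuration of a min-VMR word-set search."""

    k: int
    m: int
    objective: Objective = "vmr1"
    alphabet: Alphabet = field(default=RY)
    steps: int = 1_000_000  # annealing step budget
    t0_factor: float = 0.1  # initial temperature = t0_factor * initial objective
    cooling: float = 0.999  # geometric cooling applied every n-th step (see below)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in ("vmr1", "vmr2"):
            raise ValueError("objective must be 'vmr1' or 'vmr2'")
        if not 1 <= self.m <= self.alphabet.size**self.k:
            raise ValueError(f"set size m={self.m} out of range for k={self.k}")


@dataclass(frozen=True)
class SearchResult:
    """Best word set found, its objective value, and (exhaustive only) all ties."""

    word_set: WordSet
    value: float
    optima: tuple[WordSet, ...] = ()
    ties_truncated: bool = False


def score_wordset(ws: WordSet, objective: Objective) -> float:
    """Objective dispatcher: VMR1 or VMR2 of a word set."""
    if objective == "vmr1":
        return vmr1(ws)
    if objective == "vmr2":
        return vmr2(ws)
    raise ValueError(f"unknown objective {objective!r}")


def _pair_matrix(words: list[str], alphabet: Alphabet, weighted: bool) -> np.ndarray:
    """c[i, j] = overlap contribution of the ordered pair (words[i], words[j])."""
    k = len(words[0])
    n = len(words)
    full = np.array([word_prob(w, alphabet) for w in words])
    c = np.zeros((n, n))
    for i, v in enumerate(words):
        for j, w in enumerate(words):
            tot = 0.0
            for lag in range(1, k):
                if overlap_indicator(v, w, k - lag):
                    term = prefix_prob(v, lag, alphabet) * full[j]
                    tot += (k - lag) * term if weighted else term
            c[i, j] = tot
    return c


def _objective_from_overlap(t_sum: float, cfg: SearchConfig) -> float:
    """Map the pairwise overlap total T(S) to the VMR objective (uniform probs)."""
    p = cfg.m * (1.0 / cfg.alphabet.size) ** cfg.k
    if cfg.objective == "vmr1":
        return 1.0 - (2 * cfg.k - 1) * p + 2.0 * t_sum / p
    kp = cfg.k * p
    return 1.0 - kp + 2.0 * t_sum / kp


def _overlap_arrays(cfg: SearchConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    words = all_words(cfg.alphabet, cfg.k)
    c = _pair_matrix(words, cfg.alphabet, weighted=(cfg.objective == "vmr2"))
    diag = np.diag(c).copy()
    off = c + c.T
    np.fill_diagonal(off, 0.0)
    return words, diag, off


@njit(cache=False)
def _exhaustive_kernel(off, diag, m, eps, max_ties):  # pragma: no cover - jitted
    n = diag.shape[0]
    best = 1.0e300
    ties = np.empty((max_ties, m), np.int64)
    n_ties = 0
    overflow = False
    idx = np.empty(m, np.int64)
    cum = np.zeros((m + 1, n))
    tot = np.zeros(m + 1)
    depth = 0
    idx[0] = -1
    while depth >= 0:
        idx[depth] += 1
        v = idx[depth]
        if v > n - m + depth:
            depth -= 1
            continue
        t = tot[depth] + diag[v] + cum[depth, v]
        if t > best + eps:  # all additions are nonnegative
            continue
        if depth == m - 1:
            if t < best - eps:
                best = t
                n_ties = 0
                overflow = False
            if abs(t - best) <= eps:
                if n_ties < max_ties:
                    ties[n_ties] = idx
                    n_ties += 1
                else:
                    overflow = True
            continue
        tot[depth + 1] = t
        for u in range(n):
            cum[depth + 1, u] = cum[depth, u] + off[v, u]
        depth += 1
        idx[depth] = idx[depth - 1]
    return best, ties, n_ties, overflow


def exhaustive_min_vmr(cfg: SearchConfig, max_evaluations: int = MAX_EVALUATIONS) -> SearchResult:
    """Global minimum of the objective over all m-subsets of length-k words.

    Returns every tied global optimum (up to a cap); the reported word set
    is the lexicographically smallest optimum.  Requires uniform letter
    probabilities (where p is constant across subsets) and a candidate
    count ``C(a**k, m)`` below `max_evaluations`.
    """
    if not cfg.alphabet.is_uniform():
        raise ValueError("exhaustive search requires uniform letter probabilities")
    n = cfg.alphabet.size**cfg.k
    n_subsets = comb(n, cfg.m)
    if n_subsets > max_evaluations:
        raise ValueError(
            f"C({n}, {cfg.m}) = {n_subsets} candidate sets exceed the capacity guard "
            f"({max_evaluations}); use anneal_min_vmr instead"
        )
    words, diag, off = _overlap_arrays(cfg)
    best_t, ties, n_ties, overflow = _exhaustive_kernel(
        off, diag, cfg.m, _TIE_EPS, MAX_TIES
    )
    optima = tuple(
        sorted(
            (
                WordSet(tuple(words[j] for j in ties[i]), cfg.alphabet)
                for i in range(n_ties)
            ),
            key=lambda ws: ws.words,
        )
    )
    value = _objective_from_overlap(best_t, cfg)
    return SearchResult(optima[0], value, optima, ties_truncated=overflow)


@njit(cache=False)
def _anneal_kernel(off, diag, members, others, slot_i, slot_j, accept_u, t0, cooling):
    # pragma: no cover - jitted
    n = diag.shape[0]
    m = members.shape[0]
    contrib = np.zeros(n)
    total = 0.0
    for a in range(m):
        v = members[a]
        total += diag[v]
        for b in range(a + 1, m):
            total += off[v, members[b]]
    for u in range(n):
        s = 0.0
        for a in range(m):
            s += off[members[a], u]
        contrib[u] = s
    best = total
    best_members = members.copy()
    temp = t0
    steps = slot_i.shape[0]
    for step in range(steps):
        i = members[slot_i[step]]
        j = others[slot_j[step]]
        delta = diag[j] - diag[i] + contrib[j] - contrib[i] - off[i, j]
        if delta <= 0.0 or (temp > 0.0 and accept_u[step] < np.exp(-delta / temp)):
            total += delta
            members[slot_i[step]] = j
            others[slot_j[step]] = i
            for u in range(n):
                contrib[u] += off[j, u] - off[i, u]
            if total < best:
                best = total
                best_members = members.copy()
        temp *= cooling
    return best, best_members


def anneal_min_vmr(cfg: SearchConfig) -> SearchResult:
    """Simulated-annealing search for a low-VMR word set.

    Metropolis random walk over m-subsets; each move swaps one member word
    for one uniformly chosen non-member.  Geometric cooling from an initial
    temperature of ``t0_factor`` times the initial objective value over the
    fixed step budget.  Reproducible given the config seed; returns the
    best-seen state (no optimality guarantee).
    """
    if not cfg.alphabet.is_uniform():
        raise ValueError("annealing search requires uniform letter probabilities")
    words, diag, off = _overlap_arrays(cfg)
    n = len(words)
    rng = np.random.default_rng(cfg.seed)
    members = rng.choice(n, size=cfg.m, replace=False).astype(np.int64)
    others = np.array(sorted(set(range(n)) - set(members.tolist())), dtype=np.int64)
    init_ws = WordSet(tuple(words[i] for i in members), cfg.alphabet)
    init_obj = score_wordset(init_ws, cfg.objective)
    if others.size == 0 or cfg.steps == 0:
        return SearchResult(init_ws, init_obj)
    # temperature acts on the objective scale; T(S) maps to the objective
    # by an affine map with positive slope, so divide out that slope
    p = cfg.m * (1.0 / cfg.alphabet.size) ** cfg.k
    slope = 2.0 / p if cfg.objective == "vmr1" else 2.0 / (cfg.k * p)
    t0 = cfg.t0_factor * max(init_obj, 1e-9) / slope
    slot_i = rng.integers(0, cfg.m, size=cfg.steps)
    slot_j = rng.integers(0, others.size, size=cfg.steps)
    accept_u = rng.random(cfg.steps)
    best_t, best_members = _anneal_kernel(
        off, diag, members, others, slot_i, slot_j, accept_u, t0, cfg.cooling
    )
    ws = WordSet(tuple(words[i] for i in best_members), cfg.alphabet)
    return SearchResult(ws, _objective_from_overlap(best_t, cfg))
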