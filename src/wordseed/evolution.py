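"""Tamura (1992) DNA substitution model: matrices and pair simulation.

The T92 model is a reversible continuous-time Markov model on (a, c, g, t)
with two free parameters: the stationary G+C fraction θ and the
transition/transversion rate ratio κ.  The stationary distribution is
π = ((1-θ)/2, θ/2, θ/2, (1-θ)/2) and the rate of substituting letter i by
letter j is proportional to π_j, scaled by κ when i→j is a transition
(a↔g or c↔t).  The rate matrix is normalized so one unit of time equals
one expected substitution per site at stationarity; divergence is then
expressed as a PAM distance — expected substitutions per 100 sites — and
the substitution probability matrix is P(t) = expm(Q t) at t = pam/100.

At θ = 0.5 the model reduces to Kimura's two-parameter model (and to
Jukes–Cantor when additionally κ = 1), which provides closed-form oracles.

Sequence pairs are simulated by drawing an ancestor from π and evolving
one branch of total length t; by time-reversibility this is equivalent to
evolving both branches from a common ancestor for a total of t.
Substitution only — no indels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "T92Params",
    "SequencePair",
    "stationary_distribution",
    "rate_matrix",
    "t92_matrices",
    "expected_identity",
    "expected_ti_tv",
    "simulate_pair",
    "simulate_pair_codes",
    "mutate_sequence",
    "mutate_codes",
]

LETTERS = "acgt"
_TRANSITION_PARTNER = np.array([2, 3, 0, 1])  # a<->g, c<->t


@dataclass(frozen=True)
class T92Params:
    """gc: stationary G+C fraction in (0,1); kappa: transition/transversion
    rate ratio > 0; pam: substitutions per 100 sites, >= 0."""

    gc: float = 0.5
    kappa: float = 1.0
    pam: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.kappa <= 0.0:
            raise ValueError("kappa must be positive")
        if self.pam < 0.0:
            raise ValueError("pam must be >= 0")


@dataclass(frozen=True)
class SequencePair:
    """Two equal-length DNA sequences related by the T92 process."""

    seq_a: str
    seq_b: str
    params: T92Params

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("pair members must have equal length")


def stationary_distribution(params: T92Params) -> np.ndarray:
    theta = params.gc
    return np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])


def rate_matrix(params: T92Params) -> np.ndarray:
    """Normalized T92 rate matrix (one expected substitution per site per
    unit time at stationarity)."""
    pi = stationary_distribution(params)
    q = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            if _TRANSITION_PARTNER[i] == j:
                rate *= params.kappa
            q[i, j] = rate
        q[i, i] = 0.0
        q[i, i] = -q[i].sum()
    mu = -(pi * np.diag(q)).sum()
    return q / mu


def t92_matrices(params: T92Params) -> tuple[np.ndarray, np.ndarray]:
    """(stationary distribution, substitution probability matrix P(pam/100))."""
    pi = stationary_distribution(params)
    t = params.pam / 100.0
    p = expm(rate_matrix(params) * t) if t > 0 else np.eye(4)
    return pi, p


def expected_identity(params: T92Params) -> float:
    """Probability that a site is identical in the two sequences."""
    pi, p = t92_matrices(params)
    return float((pi * np.diag(p)).sum())


def expected_ti_tv(params: T92Params) -> float:
    """Expected transitions per transversion among differing sites."""
    pi, p = t92_matrices(params)
    ti = sum(pi[i] * p[i, _TRANSITION_PARTNER[i]] for i in range(4))
    tv = sum(
        pi[i] * p[i, j]
        for i in range(4)
        for j in range(4)
        if j != i and j != _TRANSITION_PARTNER[i]
    )
    if tv == 0.0:
        return float("inf") if ti > 0 else float("nan")
    return float(ti / tv)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def simulate_pair_codes(
    n_pairs: int,
    length: int,
    params: T92Params,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched pair simulation as (n_pairs, length) uint8 code arrays."""
    if length < 1:
        raise ValueError("length must be >= 1")
    gen = _as_rng(rng)
    pi, p = t92_matrices(params)
    a = gen.choice(4, size=(n_pairs, length), p=pi).astype(np.uint8)
    b = np.empty_like(a)
    for letter in range(4):
        mask = a == letter
        b[mask] = gen.choice(4, size=int(mask.sum()), p=p[letter]).astype(np.uint8)
    return a, b


def simulate_pair(
    length: int, params: T92Params, rng: np.random.Generator | int | None = None
) -> SequencePair:
    """One random pair: ancestor from π, partner via P(pam/100) site-wise."""
    a, b = simulate_pair_codes(1, length, params, rng)
    to_str = lambda row: "".join(LETTERS[c] for c in row)
    return SequencePair(to_str(a[0]), to_str(b[0]), params)


def mutate_codes(
    codes: np.ndarray, params: T92Params, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Apply P(pam/100) site-wise to a code array; codes >= 4 pass through."""
    gen = _as_rng(rng)
    _, p = t92_matrices(params)
    out = np.array(codes, dtype=np.uint8, copy=True)
    for letter in range(4):
        mask = codes == letter
        out[mask] = gen.choice(4, size=int(mask.sum()), p=p[letter]).astype(np.uint8)
    return out


def mutate_sequence(
    seq: str, params: T92Params, rng: np.random.Generator | int | None = None
) -> str:
    """Mutate an arbitrary DNA string; non-acgt letters are unchanged."""
    from .schemes import encode

    codes = encode(seq)
    out = mutate_codes(codes, params, rng)
    return "".join(
        LETTERS[c] if c < 4 else seq[i] for i, c in enumerate(out)
    )
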