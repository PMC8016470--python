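# Methods

This note records the models, conventions and numerical choices behind
`wordseed`, and what the synthetic benchmark does and does not show.

## Occurrence statistics

For a set of distinct length-k words over an alphabet with i.i.d. letter
probabilities, let I_j indicate that some word starts at position j and
X = Σ I_j.  With p the total per-position word probability:

- linear sequence, s ≥ k:  E[X] = (s−k+1)p;
- circular, s ≥ 2k−1:  E[X] = sp.

E[I_i I_j] depends only on the lag l = |i−j|: it is p at l = 0, p² at
l ≥ k, and for 0 < l < k a sum over ordered word pairs (V, W) of
B(V,W,k−l)·P_V(l)·P_W(k), where B(V,W,m) = 1 iff the length-m suffix of V
equals the length-m prefix of W and P_W(n) is the probability of W's first
n letters.  Collecting terms gives closed-form variances for the linear
case (valid for s ≥ 2k−2), the circular case (s ≥ 2k−1) and the shortest
linear case s = 2k−1 at which every overlap lag contributes.  For
k ≤ s < 2k−2 the package falls back to direct O(s²) summation of the
double sum (a flagged slow path).  All three forms are validated in the
tests against exhaustive enumeration of every length-s sequence (binary
alphabet, small s) and against Monte-Carlo simulation.

Two dispersion measures summarize a word set independent of s:
**VMR1** = circular Var/E (the s factor cancels; also the s→∞ limit of the
linear ratio) and **VMR2** = linear Var/E at s = 2k−1.  For a
non-overlapping set VMR1 = 1 − (2k−1)p exactly.  Degenerate sets with
p = 0 (possible only with zero-probability letters) return VMR 0 with a
warning.  Everything is computed in double precision with word-level
products; results are exact to well below the 3-decimal precision at
which designed sets are cataloged.

Word sets over the binary ry alphabet (probabilities ½/½) give identical
VMRs to their DNA expansions at 50% G+C; the binary form is the default
for design because it is 2^k-fold smaller.

## Word-set construction and search

*Two-subset construction.*  Splitting the alphabet into S1 and S2 and
fixing a prefix length j, the words whose first j letters are from S1,
whose (j+1)-th and k-th letters are from S2, and whose positions j+1..k
contain no run of ≥ j letters from S1, are pairwise non-overlapping.  For
DNA with S1 = {a}, j = 1 this is the `abb…b` family (3^(k−1) words); with
S1 = {a,g}, k = 2 it is the ry words.

*Maximum sets.*  The maximum number of pairwise non-overlapping length-k
words is found exactly: words with a self-overlap are discarded (they can
never participate), the compatibility graph joins two words that overlap
in neither direction, and an exact branch-and-bound maximum-clique solver
(networkx `max_weight_clique`) is run on it.  Enumeration is guarded at
a^k ≤ 65536; solve time, not enumeration, is the practical limit (DNA
k = 4 takes well under a second, k = 5 a few seconds, k = 6 much longer —
the known k = 6 maximum, 251, exceeds the 243 of the construction).  The
solver returns one deterministic maximum clique; when several maximum
cliques exist no canonical one is promised, since only maximality is
contractual.

*Min-VMR search.*  At fixed k and set size m over a uniform alphabet,
p = m·a^(−k) is constant, and both VMRs are affine increasing functions of
the total pairwise overlap contribution T(S) — a quadratic set function
with nonnegative terms.  The exhaustive search is a depth-first
enumeration of m-subsets with incremental T and the (admissible) bound
that further additions cannot decrease T; it returns every tied global
optimum (ties capped at 512, with a truncation flag; the reported
representative is the lexicographically smallest).  The search is compiled
with numba; k = 5, m = 8 over the binary alphabet (10.5 M subsets) takes
seconds.  Simulated annealing covers larger instances: moves swap one
member for one uniformly drawn non-member, Metropolis acceptance at
temperature T with geometric cooling (T ← 0.999·T per step) from
T0 = 0.1 × the initial objective, default budget 10^6 steps, all
parameters and the seed in the config.  The annealer returns the
best-seen state and guarantees nothing about global optimality; tests
only assert it never beats the exhaustive optimum and is reproducible.

Lower VMR does **not** always mean higher seeding sensitivity; the package
deliberately does not assert that implication anywhere.

## Subset-seed patterns

Each pattern position carries a partial equivalence relation on
{a, c, g, t}: `A/C/G/T` (that letter only), `N` (any match), `n`
(anything), `R/r` and `Y/y` (purines/pyrimidines, strict or forgiving),
and `@` (any match or transition — transversions excluded by a literal
reading of "match or transition").  Relations are validated to be
symmetric, reflexive on their allowed letters, and transitive; the
resulting partition into match classes is what allows hit counting by key
grouping.  Sparsity is 1/p(a random word is self-compatible) and weight
is log p(match | self-compatible)/log p(two letters equal), computed
position-wise (a match implies self-compatibility, so the conditional
factorizes).  Non-uniform letter frequencies are supported; the default is
uniform DNA, under which an all-`N` pattern of length L has sparsity 1 and
weight L.  The shipped pattern library (weights 5–14, ry- and
ryy-anchored) was designed externally; this package evaluates patterns
but does not design them.

## Seeding schemes

Coordinates are 0-based, half-open throughout.

*Minimizers.*  A position is selected if it is minimal in some window of w
consecutive candidate positions (windows fully inside the sequence by
default; an option adds the truncated end windows).  Orderings compare
the *suffixes* starting at each position through per-depth letter ranks:
alphabetic; `cg` (c<a<t<g at odd depths, g<t<a<c at even depths, so
`cgcg…` is the minimum sequence); `abb` (a<c<g<t at depth 1, then
t=g=c<a).  Comparisons are truncated at a fixed horizon of 24 letters and
fall back to position index (smaller index first); 24 was chosen so one
truncated suffix packs into a single base-6 unsigned 64-bit key (ranks
0–3, ambiguous letters 4, past-the-end 5), which makes window minima a
vectorized argmin.  The scalar comparator uses the same horizon, so the
fast path and the brute-force per-window oracle agree exactly; the
horizon only matters when suffixes tie 24 deep, which for the abb
ordering (the most tie-prone) happens with probability (5/8)^23 ≈ 2·10^-5
per pair on random DNA.  A hash ordering on fixed-length k-mers (default
15) uses a splitmix64-style mix of the 2-bit encoding XORed with a user
seed; it reproduces the 2/(w+1) expected density of random orderings but
is not a bit-for-bit replica of any particular tool's hash.  Ambiguous
letters rank above all real letters and invalid k-mers rank last.

*Word restriction* selects positions where any catalog word occurs
(degenerate class words are expanded to DNA k-mer codes); *every-nth*
selects positions 0, n, 2n, … of one sequence only, since striding both
sequences would miss homologies whose coordinates differ by less than the
stride.  Density is |selected| / usable candidate positions and sparsity
its reciprocal.  One caveat inherited from the design: word selection is a
deterministic function of the seed's own prefix, so restricting *both*
sequences divides random hit counts by the sparsity factor (not its
square) — exactly the hit count of every-nth seeding at the same
sparsity.  Minimizer selection at a matched density costs slightly fewer
random hits because it also depends on sequence context outside the seed.

## Substitution model

T92: stationary distribution ((1−θ)/2, θ/2, θ/2, (1−θ)/2) for (a,c,g,t);
rate i→j proportional to π_j, multiplied by κ for transitions (a↔g, c↔t);
the matrix is normalized to one expected substitution per site per unit
time at stationarity, and PAM distance d means t = d/100.  P(t) is
computed with scipy's `expm` (the matrix is tiny; an explicit
eigendecomposition would be equivalent).  At θ = 0.5 the model reduces to
Kimura's two-parameter model, whose closed forms serve as the independent
test oracle; κ = 1 additionally gives Jukes–Cantor.  Pairs are simulated
as ancestor-at-stationarity plus one branch of length t, which by
reversibility equals a two-branch tree of total length t.  Substitutions
only — no indels, no rate heterogeneity.

## Benchmark

A pair is *found* when a scheme-selected coordinate (one sequence for
every-nth, both for word/minimizer schemes; the restricted side of
every-nth is sequence 1 by convention) carries a seed match at the same
coordinate of both sequences.  Default study conditions follow the
simulation design the package reproduces: sequence length 100, 50% G+C,
κ = 1, PAM 20; the CLI default is 100 000 pairs.  Specificity counts seed
matches between two unrelated random sequences (default 10^6) by grouping
selected positions on their seed key — the exact k-mer for exact seeds,
the per-position match-class projection for pattern seeds.

Test replication is scaled to effect size: strong orderings (ry vs rr
words, abb vs avv, minimizer ordering comparisons at matched sparsity,
word-vs-alphabetic-minimizer) use 2×10^4 pairs with paired
(McNemar-style) one-sided tests at α = 0.01; the two small-margin
comparisons (the minimal-VMR k=4 set vs `rynn`, and ry words vs cg
minimizers) use the full 10^5-pair replication of the original design,
paired over shared simulated pairs and combined across seed lengths
10–14 (respectively 10–12), giving z ≈ 5 with comfortable margin.  The
every-2nd-vs-every-1st claim is checked structurally — an (ℓ+1)-mer match
anywhere implies an ℓ-mer match at an even coordinate, so found(n=2, ℓ) ⊇
found(n=1, ℓ+1) pair by pair — plus a chord test placing the n=2 point on
or above the n=1 sensitivity/hit-count curve between its bracketing hit
counts.

## What the synthetic data does and does not show

The generator produces i.i.d. sequences and substitution-only homology at
stationarity.  It reproduces the regime in which the design claims hold:
near-equal r/y frequencies, no indels, no repeats.  Real DNA violates all
three — repeats especially, since word-restricted seeding has no upper
bound on the gap between words in low-complexity sequence (homopolymer
and tandem-repeat tracts can starve or flood the selection).  Passing
tests therefore demonstrate the combinatorial and statistical claims, not
end-to-end alignment performance on genomes; FASTA input is supported for
running the same measurements on real sequences.

## Problem sizes

Defaults used by the test suite: exhaustive clique search up to DNA k = 4
(k = 5–6 reachable by raising the enumeration/time budget); exhaustive
min-VMR search up to C(32, 8) subsets; density measurements on 10^5–10^6
bases; sensitivity at 2×10^4 pairs (10^5 for the two small-margin
comparisons); Monte-Carlo occurrence checks at 10^5 trials per word set.
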