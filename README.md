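# wordseed

Minimally overlapping word sets for sparse alignment seeding.

## The problem

Sequence similarity search at scale runs on *seeds*: short, quickly
detectable similarities (typically exact k-mer matches) that anchor
alignments.  For huge data, seeds are taken only at a *sparse* subset of
sequence positions.  One simple and effective way to pick that subset is
**word-restricted seeding**: only use seeds starting at positions of
certain words, e.g. `ac`, `at`, `gc`, `gt` — sparsity 4 in *both*
sequences.  Not all word sets are equal: words that cannot overlap each
other occur anti-clumped (under-dispersed) in random sequence, spreading
the selected positions more evenly and raising the chance that a short
homologous segment contains a seed.

`wordseed` provides, for users building or tuning alignment/seeding tools:

- **Exact occurrence statistics.**  For a set of length-k words with total
  per-position probability p in an i.i.d. length-s sequence, the expected
  occurrence count is E[X] = (s−k+1)p (linear) or sp (circular), and the
  variance involves a sum over ordered word pairs (V, W) and lags
  l = 1..k−1 of overlap terms B(V,W,k−l)·P_V(l)·P_W(k), where B indicates
  that the length-(k−l) suffix of V equals the prefix of W.  Two
  length-free variance-to-mean ratios summarize clumping: VMR1 (circular /
  long-sequence limit) and VMR2 (linear at s = 2k−1).  Non-overlapping
  sets achieve VMR1 = 1 − (2k−1)p < 1.
- **Word-set design.**  The two-subset construction of non-overlapping
  words (`abb…b` family), exact maximum non-overlapping sets by clique
  search over the word-compatibility graph, and exhaustive or
  simulated-annealing search for word sets minimizing VMR1/VMR2 over the
  binary purine/pyrimidine (`ry`) alphabet.  A catalog of designed
  minimal-VMR sets is included.
- **Generalized subset-seed patterns** such as `RYNN@@`: each position
  carries a partial equivalence relation on the DNA letters (restriction
  and/or transition tolerance), unifying word restriction with spaced and
  subset seeds, with analytic sparsity 1/p(self-compatible) and weight
  log p(match | compatible)/log p(letter match).
- **Seeding schemes**: every-nth positions, word-restricted positions, and
  minimizers (window minima under alphabetic, `cg`, `abb` or hashed k-mer
  orderings; random-ordering density 2/(w+1)).
- **A simulation benchmark**: pairs of sequences related by the T92
  substitution model (G+C content θ, transition/transversion ratio κ, PAM
  distance), seeding *sensitivity* (fraction of pairs with a seed match at
  identical coordinates) and *specificity* (random hit counts between
  unrelated megabase sequences).

## Worked example

Evaluate the designed four-word set `{rrry, ryrr, ryyr, yyyr}` (r = a/g,
y = c/t), confirm it is the exhaustive VMR2 optimum at its size, and
benchmark it:

```console
$ printf 'rrry\nryrr\nryyr\nyyyr\n' > mv4.txt
$ wordseed vmr --words mv4.txt
# words	k	sparsity	vmr1	vmr2
rrry,ryrr,ryyr,yyyr	4	4	0.25	0.34375

$ wordseed design minvmr --k 4 --m 4 --objective vmr2
# minvmr alphabet=ry k=4 m=4 objective=vmr2 method=exhaustive seed=0
# value	0.34375
rrry
ryrr
ryyr
yyyr

$ wordseed bench sensitivity --scheme word --words mv4.txt --seed-len 10 --pairs 10000 --seed 1
# version=0.1.0 gc=50.0 kappa=1.0 pam=20.0 seed=1
# scheme	seed_spec	sensitivity	n_pairs	seq_len	seed
words(rrry,ryrr,ryyr,yyyr)	exact10	0.8991	10000	100	1
```

Reading the numbers: the set has sparsity 4 (one position in four starts a
word on average) and VMR2 ≈ 0.344 — well under 1, so occurrences are
anti-clumped (the plain `rynn` restriction has VMR2 = 0.375).  With
exact-match 10-mers restricted to these words, 89.9% of simulated pairs
(length 100, PAM distance 20, κ = 1, 50% G+C) are found by at least one
seed at homologous coordinates.  Pattern evaluation works the same way:

```console
$ wordseed pattern eval --pattern RYN@@@nnNN@@@NN
# pattern	length	sparsity	weight
RYN@@@nnNN@@@NN	15	4	10
```

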