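"""Position-selection schemes against brute-force oracles."""

import functools

import numpy as np
import pytest

from wordseed.patterns import parse_pattern
from wordseed.schemes import (
    EveryNth,
    HashOrdering,
    MinimizerSelect,
    PatternRestricted,
    SuffixOrdering,
    WordRestricted,
    compare_suffixes,
    density,
    encode,
    make_ordering,
    minimizer_positions,
    select_every_nth,
    select_pattern_positions,
    select_word_positions,
    sparsity,
)

ALL_ORDERINGS = [
    SuffixOrdering("alphabetic"),
    SuffixOrdering("cg"),
    SuffixOrdering("abb"),
    HashOrdering(k=5, seed=7),
]


def brute_force_minimizers(seq: str, w: int, ordering) -> np.ndarray:
    """Naive per-window scan using the scalar suffix comparator."""
    codes = encode(seq)
    n_cand = ordering.num_candidates(len(codes))

    def less(i, j):
        c = compare_suffixes(codes, i, j, ordering)
        return c < 0 or (c == 0 and i < j)

    picks = set()
    for start in range(n_cand - w + 1):
        best = start
        for i in range(start + 1, start + w):
            if less(i, best):
                best = i
        picks.add(best)
    return np.array(sorted(picks))


def random_dna(rng, n):
    return "".join(rng.choice(list("acgt"), size=n))


class TestEveryNth:
    def test_examples(self):
        assert select_every_nth(10, 3).tolist() == [0, 3, 6, 9]
        assert select_every_nth(5, 1).tolist() == [0, 1, 2, 3, 4]

    def test_density_is_inverse_n(self):
        pos = select_every_nth(8000, 8)
        assert density(pos, 8000) == pytest.approx(1 / 8)
        assert sparsity(pos, 8000) == pytest.approx(8)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            select_every_nth(10, 0)


class TestWordPositions:
    def test_scan_example(self):
        assert select_word_positions("acgt", ("ry",)).tolist() == [0, 2]

    def test_all_words_selects_everything(self):
        pos = select_word_positions("acgtacgt", ("nn",))
        assert pos.tolist() == list(range(7))

    def test_matches_naive_scan(self, rng):
        seq = random_dna(rng, 500)
        from wordseed.words import expand_class_word

        words = set(expand_class_word("rry").words)
        expected = [i for i in range(len(seq) - 2) if seq[i : i + 3] in words]
        assert select_word_positions(seq, ("rry",)).tolist() == expected

    def test_ambiguous_letters_never_seed(self):
        pos = select_word_positions("acnngt", ("ry",))
        assert pos.tolist() == [0, 4]  # windows containing 'n' are skipped
        pos = select_word_positions("acgtnn", ("ry",))
        assert pos.tolist() == [0, 2]

    def test_density_converges_to_total_probability(self, rng):
        seq = random_dna(rng, 200_000)
        pos = select_word_positions(seq, ("abb",))
        p = 9 / 64
        usable = len(seq) - 2
        se = np.sqrt(p * (1 - p) / usable)
        # occurrences are anti-clumped, so the binomial SE is conservative
        assert abs(density(pos, usable) - p) < 3 * se


class TestOrderings:
    def test_alphabetic_compare(self):
        codes = encode("acgact")
        assert compare_suffixes(codes, 0, 3, SuffixOrdering("alphabetic")) == -1

    def test_cg_minimum_sequence(self):
        # cgcg... is the minimum sequence under the cg order
        seq = "cgcgtacg"
        o = SuffixOrdering("cg")
        for j in range(1, 5):
            assert compare_suffixes(seq, 0, j, o) == -1

    def test_abb_order_example(self):
        # a < t at depth 1; t = g = c at later depths
        o = SuffixOrdering("abb")
        assert compare_suffixes("atttaa", 0, 3, o) == -1  # 'att...' < 'taa'
        # g and t tie at depth 2, so the depth-3 c-vs-a decides
        assert compare_suffixes("agcata", 0, 3, o) == -1

    def test_abb_order_deep_tie_falls_back(self):
        # identical down to the comparison horizon: reported as a tie,
        # which minimizer selection resolves by position index
        o = SuffixOrdering("abb")
        assert compare_suffixes("t" * 30, 0, 1, o) == 0

    def test_keys_agree_with_comparator(self, rng):
        seq = random_dna(rng, 200)
        codes = encode(seq)
        for ordering in ALL_ORDERINGS:
            keys = ordering.keys(codes)
            n = len(keys)
            idx = rng.integers(0, n, size=200)
            jdx = rng.integers(0, n, size=200)
            for i, j in zip(idx, jdx):
                c = compare_suffixes(codes, int(i), int(j), ordering)
                if c < 0:
                    assert keys[i] < keys[j]
                elif c > 0:
                    assert keys[i] > keys[j]
                else:
                    assert keys[i] == keys[j]


class TestMinimizers:
    def test_w1_selects_all(self):
        seq = "acgtacgtac"
        pos = minimizer_positions(seq, 1, SuffixOrdering("alphabetic"))
        assert pos.tolist() == list(range(10))

    @pytest.mark.parametrize("ordering", ALL_ORDERINGS, ids=lambda o: getattr(o, "kind", "hash"))
    @pytest.mark.parametrize("w", [2, 5, 13])
    def test_matches_brute_force(self, rng, ordering, w):
        for trial in range(3):
            seq = random_dna(rng, 300)
            got = minimizer_positions(seq, w, ordering)
            want = brute_force_minimizers(seq, w, ordering)
            np.testing.assert_array_equal(got, want)

    def test_repetitive_sequence_matches_brute_force(self):
        seq = "a" * 50 + "acgt" * 20 + "t" * 30
        for ordering in ALL_ORDERINGS:
            got = minimizer_positions(seq, 8, ordering)
            want = brute_force_minimizers(seq, 8, ordering)
            np.testing.assert_array_equal(got, want)

    def test_density_decreases_with_w(self, rng):
        seq = random_dna(rng, 30_000)
        for ordering in (SuffixOrdering("alphabetic"), SuffixOrdering("cg"), SuffixOrdering("abb")):
            last = 1.1
            for w in (2, 4, 8, 16, 30):
                d = density(minimizer_positions(seq, w, ordering), len(seq))
                assert d < last
                last = d

    def test_ordering_density_ranking(self, rng):
        # alphabetic minimizers are densest; abb sparsest for w > 10
        seq = random_dna(rng, 100_000)
        w = 16
        d = {
            kind: density(minimizer_positions(seq, w, SuffixOrdering(kind)), len(seq))
            for kind in ("alphabetic", "cg", "abb")
        }
        assert d["alphabetic"] > d["cg"] > d["abb"]

    def test_hash_density_formula(self, rng):
        seq = random_dna(rng, 200_000)
        o = HashOrdering(k=15, seed=3)
        w = 10
        d = density(minimizer_positions(seq, w, o), o.num_candidates(len(seq)))
        assert d == pytest.approx(2 / (w + 1), rel=0.02)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            minimizer_positions("acg", 5, SuffixOrdering("alphabetic"))

    def test_end_windows_option_adds_tail_positions(self):
        seq = "tttttacg"
        o = SuffixOrdering("alphabetic")
        base = set(minimizer_positions(seq, 4, o).tolist())
        extended = set(minimizer_positions(seq, 4, o, include_end_windows=True).tolist())
        assert base <= extended


class TestPatternSelection:
    def test_unifies_with_word_selection(self, rng):
        # a pattern with a restricted RY prefix selects exactly the ry-word positions
        seq = random_dna(rng, 2000)
        pat = parse_pattern("RYnn")
        from_pattern = select_pattern_positions(seq, pat)
        from_words = select_word_positions(seq, ("ry",))
        limit = len(seq) - pat.length + 1
        np.testing.assert_array_equal(from_pattern, from_words[from_words < limit])

    def test_scheme_masks_agree_with_positions(self, rng):
        seq = random_dna(rng, 400)
        codes = encode(seq)[None, :]
        schemes = [
            EveryNth(4),
            WordRestricted(("ry",)),
            PatternRestricted(parse_pattern("RYnn")),
            MinimizerSelect(SuffixOrdering("cg"), 6),
            MinimizerSelect(HashOrdering(k=5, seed=1), 6),
        ]
        for scheme in schemes:
            mask = scheme.selection_mask(codes)[0]
            np.testing.assert_array_equal(np.flatnonzero(mask), scheme.positions(codes[0]))


class TestDensity:
    def test_empty_selection(self):
        assert density(np.array([]), 100) == 0.0
        assert sparsity(np.array([]), 100) == float("inf")
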