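"""Occurrence-count statistics against exhaustive and Monte-Carlo oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wordseed.alphabet import Alphabet, DNA, RY
from wordseed.occurrence import (
    empirical_occurrence_stats,
    occurrence_mean,
    occurrence_variance,
    vmr1,
    vmr2,
)
from wordseed.words import WordSet, all_words, expand_class_word, is_non_overlapping_set, total_prob


def exhaustive_moments(ws: WordSet, s: int, topology: str) -> tuple[float, float]:
    """Exact E[X], Var[X] by enumerating every length-s sequence.

    Independent oracle: counts word occurrences by direct string scanning,
    weighting each sequence by its probability.
    """
    alpha = ws.alphabet
    prob = dict(zip(alpha.letters, alpha.probs))
    k = ws.k
    words = set(ws.words)
    e1 = e2 = 0.0
    for seq_tuple in itertools.product(alpha.letters, repeat=s):
        seq = "".join(seq_tuple)
        scan = seq + seq[: k - 1] if topology == "circular" else seq
        n_pos = s if topology == "circular" else s - k + 1
        x = sum(1 for i in range(n_pos) if scan[i : i + k] in words)
        p_seq = math.prod(prob[c] for c in seq)
        e1 += p_seq * x
        e2 += p_seq * x * x
    return e1, e2 - e1 * e1


binary_sets = st.lists(
    st.text(alphabet="ry", min_size=3, max_size=3), min_size=1, max_size=3, unique=True
).map(lambda ws: WordSet(tuple(ws), RY))


class TestAgainstExhaustiveEnumeration:
    @pytest.mark.parametrize(
        "words, s, topology",
        [
            (("ry",), 3, "linear"),
            (("ry",), 6, "circular"),
            (("rr", "ry"), 5, "linear"),
            (("ryr", "yyy"), 7, "linear"),
            (("ryr", "yyy"), 7, "circular"),
            (("ryry",), 7, "linear"),  # s = 2k-1
            (("ryry", "yryr"), 5, "linear"),  # s < 2k-2: slow path
            (("rrr",), 3, "linear"),  # s < 2k-2: slow path
        ],
    )
    def test_mean_and_variance(self, words, s, topology):
        ws = WordSet(words, RY)
        mean, var = exhaustive_moments(ws, s, topology)
        assert occurrence_mean(ws, s, topology) == pytest.approx(mean, abs=1e-12)
        assert occurrence_variance(ws, s, topology) == pytest.approx(var, abs=1e-12)

    def test_biased_alphabet(self):
        alpha = Alphabet(("r", "y"), (0.3, 0.7))
        ws = WordSet(("ry", "yy"), alpha)
        mean, var = exhaustive_moments(ws, 6, "linear")
        assert occurrence_mean(ws, 6) == pytest.approx(mean)
        assert occurrence_variance(ws, 6) == pytest.approx(var)

    @given(ws=binary_sets)
    def test_random_sets_at_short_linear_length(self, ws):
        s = 2 * ws.k - 1
        mean, var = exhaustive_moments(ws, s, "linear")
        assert occurrence_mean(ws, s) == pytest.approx(mean, abs=1e-12)
        assert occurrence_variance(ws, s) == pytest.approx(var, abs=1e-12)
        assert vmr2(ws) == pytest.approx(var / mean, abs=1e-12)


class TestMeanFormulas:
    def test_linear(self):
        ws = WordSet(("ry",), RY)
        assert occurrence_mean(ws, 3) == pytest.approx(0.5)

    def test_circular(self):
        ws = expand_class_word("ry", DNA)
        assert occurrence_mean(ws, 100, "circular") == pytest.approx(25.0)

    def test_certain_word_set(self):
        ws = WordSet(tuple(all_words(RY, 2)), RY)  # p = 1
        assert occurrence_mean(ws, 10) == pytest.approx(9.0)

    def test_linear_in_s(self):
        ws = WordSet(("ryr",), RY)
        m1, m2 = occurrence_mean(ws, 50), occurrence_mean(ws, 100)
        assert (m2 - m1) == pytest.approx(50 * total_prob(ws))

    def test_too_short_raises(self):
        ws = WordSet(("ryr",), RY)
        with pytest.raises(ValueError):
            occurrence_mean(ws, 2)
        with pytest.raises(ValueError):
            occurrence_variance(ws, 4, "circular")


class TestVMR:
    def test_non_overlapping_closed_form(self):
        # for a non-overlapping set the circular VMR is 1 - (2k-1)p
        for word in ("ry", "ryy", "ryyy"):
            ws = expand_class_word(word, RY)
            assert is_non_overlapping_set(ws)
            p = total_prob(ws)
            assert vmr1(ws) == pytest.approx(1 - (2 * ws.k - 1) * p)
            assert vmr1(ws) < 1.0

    def test_vmr2_equals_linear_ratio_at_2k_minus_1(self):
        ws = WordSet(("rrry", "ryrr", "ryyr", "yyyr"), RY)
        s = 2 * ws.k - 1
        ratio = occurrence_variance(ws, s) / occurrence_mean(ws, s)
        assert vmr2(ws) == pytest.approx(ratio, abs=1e-12)

    def test_linear_vmr_converges_to_vmr1(self):
        ws = WordSet(("ryry", "rryy"), RY)
        target = vmr1(ws)
        prev_err = float("inf")
        for s in (10**3, 10**4, 10**6):
            ratio = occurrence_variance(ws, s) / occurrence_mean(ws, s)
            err = abs(ratio - target)
            assert err < prev_err
            prev_err = err
        # the gap decays as c/s with c of order 1 for this set
        assert prev_err < 5e-6

    def test_circular_vmr_independent_of_s(self):
        ws = WordSet(("ryr",), RY)
        r1 = occurrence_variance(ws, 10, "circular") / occurrence_mean(ws, 10, "circular")
        r2 = occurrence_variance(ws, 1000, "circular") / occurrence_mean(ws, 1000, "circular")
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(vmr1(ws), abs=1e-12)

    def test_zero_probability_set_warns(self):
        alpha = Alphabet(("r", "y"), (1.0, 0.0))
        ws = WordSet(("y",), alpha)
        with pytest.warns(UserWarning, match="zero occurrence"):
            assert vmr1(ws) == 0.0

    @given(ws=binary_sets)
    def test_variance_nonnegative(self, ws):
        assert occurrence_variance(ws, 50) >= -1e-9
        assert occurrence_variance(ws, 50, "circular") >= -1e-9


class TestEmpirical:
    def test_matches_analytic_circular(self, rng):
        ws = expand_class_word("ry", RY)
        stats = empirical_occurrence_stats(ws, 100, "circular", trials=20_000, rng=rng)
        mean = occurrence_mean(ws, 100, "circular")
        var = occurrence_variance(ws, 100, "circular")
        se_mean = math.sqrt(var / stats.trials)
        assert abs(stats.mean - mean) < 3 * se_mean

    def test_matches_analytic_linear_variance(self, rng):
        ws = expand_class_word("abb", DNA)
        s = 59
        stats = empirical_occurrence_stats(ws, s, "linear", trials=20_000, rng=rng)
        var = occurrence_variance(ws, s)
        # SE of a sample variance ~ var * sqrt(2/(n-1)) for near-normal counts;
        # inflate generously to stay conservative
        se_var = var * math.sqrt(8.0 / stats.trials)
        assert abs(stats.variance - var) < 4 * se_var

    def test_single_trial_variance_zero_with_warning(self):
        ws = WordSet(("ry",), RY)
        with pytest.warns(UserWarning, match="single-trial"):
            stats = empirical_occurrence_stats(ws, 20, trials=1, rng=0)
        assert stats.variance == 0.0

    def test_reproducible(self):
        ws = WordSet(("ryr",), RY)
        a = empirical_occurrence_stats(ws, 30, trials=100, rng=42)
        b = empirical_occurrence_stats(ws, 30, trials=100, rng=42)
        assert a == b
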