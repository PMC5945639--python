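"""Word-enrichment landscape: exactness, signs, peaks."""

import math

import numpy as np
import pandas as pd
import pytest

from ripuse.ranking import RankedList
from ripuse.wordscan import (
    decode_word,
    default_cutoffs,
    encode_word,
    hypergeom_log_tail,
    kmer_codes,
    landscape,
    presence_matrix,
    seed_profile,
    top_words,
)


def ranked(ids):
    stat = pd.Series(np.linspace(1, -1, len(ids)), index=ids)
    return RankedList(list(ids), stat, "rip_enrichment_desc")


def enum_upper(x, N, K, n):
    hi = min(K, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(x, hi + 1)) \
        / math.comb(N, n)


def enum_lower(x, N, K, n):
    lo = max(0, n - (N - K))
    return sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(lo, x + 1)) \
        / math.comb(N, n)


class TestEncoding:
    def test_round_trip(self):
        for w in ("ACGTAC", "TTTTTTT", "GATTACAA"):
            assert decode_word(encode_word(w), len(w)) == w

    def test_kmer_codes_skip_invalid_windows(self):
        codes = kmer_codes("ACGNTACGTA", 6)
        # only windows free of N: positions 4..4 ("TACGTA")
        assert [decode_word(int(c), 6) for c in codes] == ["TACGTA"]

    def test_presence_indicators_manual(self):
        M = presence_matrix(["t1"], {"t1": "TACGGGTA"}, 6)
        present = {decode_word(int(c), 6) for c in M.indices}
        assert present == {"TACGGG", "ACGGGT", "CGGGTA"}
        assert M.sum() == 3

    def test_short_utr_gives_empty_row(self):
        M = presence_matrix(["t1"], {"t1": "ACG"}, 6)
        assert M.sum() == 0

    def test_duplicate_occurrences_still_indicator_one(self):
        M = presence_matrix(["t1"], {"t1": "ACGTACACGTAC"}, 6)
        assert M[0, encode_word("ACGTAC")] == 1

    def test_missing_utr_names_transcript(self):
        with pytest.raises(KeyError, match="t2"):
            presence_matrix(["t1", "t2"], {"t1": "ACGTACGT"}, 6)


class TestLandscape:
    def test_exact_top5_example(self):
        """Word in exactly the top 5 of 10: upper p = 1/252, score ~ +2.40."""
        ids = [f"t{i:02d}" for i in range(10)]
        utrs = {t: ("AAATTTACGCAT" if i < 5 else "GGGGGGGGGGGG")
                for i, t in enumerate(ids)}
        ls = landscape(ranked(ids), utrs, k_set=(6,), cutoffs=np.array([5]))
        word = "TACGCA"
        assert ls.score(word, 5) == pytest.approx(-math.log10(1 / 252), abs=1e-9)
        t = ls.tables[6]
        assert t.raw_p[encode_word(word), 0] == pytest.approx(1 / 252, abs=1e-15)

    def test_word_in_every_transcript_scores_zero(self):
        ids = ["a", "b", "c", "d"]
        utrs = {t: "ACGTAC" for t in ids}
        ls = landscape(ranked(ids), utrs, k_set=(6,), cutoffs=np.array([1, 2, 3]))
        for c in (1, 2, 3):
            assert ls.score("ACGTAC", c) == 0.0

    def test_absent_word_p_one_everywhere(self):
        ids = ["a", "b", "c", "d"]
        utrs = {t: "ACGTAC" for t in ids}
        ls = landscape(ranked(ids), utrs, k_set=(6,), cutoffs=np.array([2]))
        t = ls.tables[6]
        assert t.raw_p[encode_word("TTTTTT"), 0] == pytest.approx(1.0)
        assert ls.score("TTTTTT", 2) == 0.0

    def test_matches_enumeration_on_small_universe(self, rng):
        """Every landscape cell equals brute-force point-mass summation."""
        N = 18
        ids = [f"t{i:02d}" for i in range(N)]
        bases = np.array(list("ACGT"))
        utrs = {t: "".join(rng.choice(bases, size=30)) for t in ids}
        cutoffs = np.array([3, 7, 11, 15])
        ls = landscape(ranked(ids), utrs, k_set=(6,), cutoffs=cutoffs)
        t = ls.tables[6]
        check = rng.choice(4**6, size=250, replace=False)
        for code in check:
            K = int(t.universe_counts[code])
            for j, n in enumerate(cutoffs):
                x = int(t.leading_counts[code, j])
                if x / n > K / N:
                    expect = enum_upper(x, N, K, int(n))
                else:
                    expect = enum_lower(x, N, K, int(n))
                assert t.raw_p[code, j] == pytest.approx(expect, abs=1e-12)

    def test_tail_sum_rule(self, rng):
        """upper + lower - point mass = 1 for arbitrary cells."""
        for _ in range(200):
            N = int(rng.integers(2, 60))
            n = int(rng.integers(1, N))
            K = int(rng.integers(0, N + 1))
            lo, hi = max(0, n - (N - K)), min(K, n)
            x = int(rng.integers(lo, hi + 1))
            up = np.exp(hypergeom_log_tail(np.array([x]), N, np.array([K]), n, True))[0]
            low = np.exp(hypergeom_log_tail(np.array([x]), N, np.array([K]), n, False))[0]
            pmf = math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
            assert up + low - pmf == pytest.approx(1.0, abs=1e-10)

    def test_reversal_antisymmetry(self):
        """Reversing the list negates the score at the complementary cutoff."""
        ids = [f"t{i:02d}" for i in range(12)]
        utrs = {t: ("CCCTACGCACCC" if i < 4 else "GGGGGGGGGGGG")
                for i, t in enumerate(ids)}
        n = 4
        fwd = landscape(ranked(ids), utrs, k_set=(6,), cutoffs=np.array([n]))
        rev = landscape(ranked(ids).reversed(), utrs, k_set=(6,),
                        cutoffs=np.array([12 - n]))
        word = "TACGCA"
        assert fwd.score(word, n) == pytest.approx(-rev.score(word, 12 - n), abs=1e-9)

    def test_cutoff_validation(self):
        ids = ["a", "b", "c"]
        utrs = {t: "ACGTACGT" for t in ids}
        with pytest.raises(ValueError):
            landscape(ranked(ids), utrs, k_set=(6,), cutoffs=np.array([3]))
        with pytest.raises(ValueError):
            landscape(ranked(ids), utrs, k_set=(6,), cutoffs=np.array([2, 2]))
        with pytest.raises(ValueError):
            landscape(ranked(ids), utrs, k_set=(5,))

    def test_default_cutoffs_grid(self):
        grid = default_cutoffs(2000)
        assert grid[0] == 100 and grid[-1] == 1900 and len(grid) == 20
        assert (np.diff(grid) > 0).all()


class TestTopWords:
    def test_bonferroni_factor(self):
        ids = [f"t{i:02d}" for i in range(10)]
        utrs = {t: ("AAATTTACGCAT" if i < 5 else "GGGGGGGGGGGG")
                for i, t in enumerate(ids)}
        cutoffs = np.array([3, 5, 7])
        ls = landscape(ranked(ids), utrs, k_set=(6,), cutoffs=cutoffs)
        tw = top_words(ls, m=4**6)
        row = tw[tw.word == "TACGCA"].iloc[0]
        assert row.corrected_p == pytest.approx(
            min(1.0, row.raw_p * (4**6) * len(cutoffs))
        )

    def test_planted_word_ranks_first(self, rng):
        """A word planted into the head of the list peaks above all others."""
        n_tx, planted = 300, 60
        ids = [f"t{i:03d}" for i in range(n_tx)]
        bases = np.array(list("ACGT"))
        word = "TACGGGT"
        utrs = {}
        for i, t in enumerate(ids):
            seq = "".join(rng.choice(bases, size=200))
            if i < planted:
                seq = seq[:50] + word + seq[50 + len(word):]
            utrs[t] = seq
        ls = landscape(ranked(ids), utrs, k_set=(7,))
        tw = top_words(ls, m=3)
        assert tw.iloc[0].word == word
        assert tw.iloc[0].corrected_p < 1e-6

    def test_m_validation(self, rng):
        ids = ["a", "b", "c"]
        utrs = {t: "ACGTACGT" for t in ids}
        ls = landscape(ranked(ids), utrs, k_set=(6,), cutoffs=np.array([1]))
        with pytest.raises(ValueError):
            top_words(ls, m=0)


class TestSeedProfile:
    def test_single_cutoff_profile(self, mir100):
        ids = [f"t{i:02d}" for i in range(10)]
        utrs = {t: ("AATACGGGTAAA" if i < 5 else "GGGGGGGGGGGG")
                for i, t in enumerate(ids)}
        ls = landscape(ranked(ids), utrs, cutoffs=np.array([5]))
        prof = seed_profile(ls, mir100)
        assert set(prof.table.site_class) == {"8mer", "7mer-m8", "7mer-1A", "6mer"}
        assert all(len(c) == 1 for c in prof.curves.values())
        # every canonical word sits in the top half here: positive peaks
        assert (prof.table.peak_score > 0).all()

    def test_skips_k_not_in_landscape(self, mir100):
        ids = [f"t{i:02d}" for i in range(10)]
        utrs = {t: "AATACGGGTAAA" for t in ids}
        ls = landscape(ranked(ids), utrs, k_set=(7,), cutoffs=np.array([5]))
        prof = seed_profile(ls, mir100)
        assert set(prof.table.site_class) == {"7mer-m8", "7mer-1A"}
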