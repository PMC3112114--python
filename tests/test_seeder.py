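"""Seed enumeration: Hamming occurrence counting, pruning soundness, ranking."""

import itertools
import math

import numpy as np
import pytest

from bismotif import SequenceSet, SeederParams, enumerate_seeds, hamming
from bismotif.core import ConfigError, FormatError
from bismotif.seeder import (
    neighborhood_size,
    read_seeds,
    sequence_hit_probability,
    significance,
)
from tests.conftest import random_sequence_set


def brute_force_supports(seqs, k, e):
    """Support of every width-k word by direct scan over all windows."""
    supports = {}
    for word_tuple in itertools.product("ACGT", repeat=k):
        word = "".join(word_tuple)
        count = 0
        for seq in seqs.seqs:
            hit = False
            for j in range(len(seq) - k + 1):
                window = seq[j : j + k]
                if "N" in window:
                    continue
                if hamming(word, window) <= e:
                    hit = True
                    break
            count += hit
        supports[word] = count
    return supports


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,d", [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("AAAA", "TTTT", 4)]
    )
    def test_examples(self, a, b, d):
        assert hamming(a, b) == d

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming("AC", "ACG")


class TestEnumerateSeeds:
    def test_exact_repeat_ranks_first(self):
        flank = "TTTTCCTTTTCC"
        seqs = SequenceSet(
            tuple(f"s{i}" for i in range(5)),
            tuple(flank + "ACGTACGT" + flank for _ in range(5)),
        )
        params = SeederParams(k=8, e=0, quorum_count=5, z_min=1, z_max=10)
        cands = enumerate_seeds(seqs, params)
        assert cands[0].word == "ACGTACGT"
        assert cands[0].support == 5

    def test_exact_match_support_counts_substring_presence(self, rng):
        seqs = random_sequence_set(rng, n_max=4, len_min=8, len_max=15)
        params = SeederParams(k=3, e=0, quorum_count=1, z_min=1, z_max=4**3)
        cands = enumerate_seeds(seqs, params)
        for c in cands:
            expected = sum(c.word in s for s in seqs.seqs)
            assert c.support == expected

    @pytest.mark.parametrize("method", ["dfs", "dense"])
    def test_matches_brute_force_enumeration(self, rng, method):
        for _ in range(25):
            seqs = random_sequence_set(rng, n_max=5, len_min=5, len_max=20)
            k = int(rng.integers(2, 5))
            e = int(rng.integers(0, 2))
            quorum = int(rng.integers(1, seqs.n_sequences + 1))
            params = SeederParams(k=k, e=e, quorum_count=quorum, z_min=1, z_max=4**k)
            cands = enumerate_seeds(seqs, params, method=method)
            oracle = brute_force_supports(seqs, k, e)
            got = {c.word: c.support for c in cands}
            expected = {w: s for w, s in oracle.items() if s >= quorum}
            if expected:  # no quorum relaxation triggered in this branch
                assert got == expected

    def test_dfs_and_dense_agree_exactly(self, rng):
        for _ in range(10):
            seqs = random_sequence_set(rng, n_max=5, len_min=6, len_max=18)
            params = SeederParams(k=3, e=1, quorum_count=2, z_min=1, z_max=200)
            a = enumerate_seeds(seqs, params, method="dfs")
            b = enumerate_seeds(seqs, params, method="dense")
            assert [(c.word, c.support, c.significance) for c in a] == [
                (c.word, c.support, c.significance) for c in b
            ]

    def test_ranking_is_deterministic_total_order(self, rng):
        seqs = random_sequence_set(rng, n_max=5, len_min=10, len_max=20)
        params = SeederParams(k=3, e=1, quorum_count=1, z_min=1, z_max=100)
        cands = enumerate_seeds(seqs, params)
        keys = [(-c.significance, -c.support, c.word) for c in cands]
        assert keys == sorted(keys)
        assert cands == enumerate_seeds(seqs, params)

    def test_quorum_relaxes_until_enough_seeds(self):
        # every sequence distinct: quorum 4 with e=0 yields nothing at first
        seqs = SequenceSet(
            ("a", "b", "c", "d"), ("AAAAAA", "CCCCCC", "GGGGGG", "TTTTTT")
        )
        params = SeederParams(k=4, e=0, quorum_count=4, z_min=2, z_max=10)
        cands = enumerate_seeds(seqs, params)
        assert len(cands) >= 2
        assert all(c.support >= 1 for c in cands)

    def test_truncated_to_z_max(self, rng):
        seqs = random_sequence_set(rng, n_max=5, len_min=15, len_max=25)
        params = SeederParams(k=2, e=1, quorum_count=1, z_min=1, z_max=5)
        assert len(enumerate_seeds(seqs, params)) == 5

    def test_k_longer_than_shortest_sequence_rejected(self):
        seqs = SequenceSet(("a",), ("ACGT",))
        with pytest.raises(ConfigError):
            enumerate_seeds(seqs, SeederParams(k=5, z_min=1))

    def test_masked_windows_never_count(self):
        seqs = SequenceSet(("a", "b"), ("AANAAAA", "AAAAAAA"))
        params = SeederParams(k=4, e=0, quorum_count=1, z_min=1, z_max=10)
        cands = {c.word: c.support for c in enumerate_seeds(seqs, params)}
        # in 'a' only the final window (start 3) avoids the masked base
        assert cands["AAAA"] == 2
        seqs_all_masked = SequenceSet(("a", "b"), ("AANAAA", "AAAAAA"))
        cands = {c.word: c.support for c in enumerate_seeds(seqs_all_masked, params)}
        assert cands["AAAA"] == 1


class TestSignificance:
    def test_neighborhood_size_closed_form(self):
        assert neighborhood_size(4, 0) == 1
        assert neighborhood_size(4, 1) == 1 + 4 * 3
        assert neighborhood_size(8, 2) == 1 + 8 * 3 + math.comb(8, 2) * 9
        assert neighborhood_size(3, 5) == 4**3  # capped at the whole space

    def test_hit_probability_matches_independent_window_model(self, rng):
        # enumerate the model the null assumes: W independent uniform windows
        k, e, n = 2, 0, 5
        w = n - k + 1
        p_word = neighborhood_size(k, e) / 4**k
        exact = 0.0
        for hits in range(1, w + 1):
            exact += (
                math.comb(w, hits) * p_word**hits * (1 - p_word) ** (w - hits)
            )
        assert sequence_hit_probability(k, e, n) == pytest.approx(exact, abs=1e-12)

    def test_monotone_in_support(self):
        lengths = [30, 40, 25]
        zs = [significance(s, 4, 1, lengths) for s in range(4)]
        assert zs == sorted(zs)
        assert all(np.isfinite(z) for z in zs)

    def test_equal_support_words_tie(self, rng):
        seqs = random_sequence_set(rng, n_max=5, len_min=10, len_max=20)
        params = SeederParams(k=3, e=1, quorum_count=1, z_min=1, z_max=300)
        by_support = {}
        for c in enumerate_seeds(seqs, params):
            by_support.setdefault(c.support, set()).add(c.significance)
        for sigs in by_support.values():
            assert len(sigs) == 1

    def test_saturated_null_degenerates_gracefully(self):
        # e >= k: every sequence hits with probability 1, variance 0
        assert significance(3, 2, 2, [10, 10, 10]) == 0.0
        assert significance(2, 2, 2, [10, 10, 10]) == -math.inf


class TestSeedsFile:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "seeds.txt"
        path.write_text("# comment\nACGT\nTTTT\n\n")
        assert read_seeds(path, 4) == ["ACGT", "TTTT"]

    def test_wrong_width_rejected(self, tmp_path):
        path = tmp_path / "seeds.txt"
        path.write_text("ACG\n")
        with pytest.raises(FormatError):
            read_seeds(path, 4)

    def test_degenerate_word_rejected(self, tmp_path):
        path = tmp_path / "seeds.txt"
        path.write_text("ACGR\n")
        with pytest.raises(FormatError):
            read_seeds(path, 4)
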