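"""Balanced information score: annotation argmax, objective value, sentinel."""

import math

import numpy as np
import pytest

from bismotif import (
    EMPTY_MOTIF,
    Motif,
    Prior,
    SequenceSet,
    annotate,
    bis,
    bis_of,
    iupac_to_pssm,
    score_word,
    uniform_prior,
)
from bismotif.scoring import BisScorer, NoAdmissibleWindowError
from tests.conftest import random_prior, random_sequence_set


def brute_force_annotation(m, seqs, priors, lam, delta, prob_floor=1e-10):
    """Independent exhaustive scan: score every admissible window directly."""
    k = m.width
    pssm = iupac_to_pssm(m, delta)
    if priors:
        raw = np.array([p.weight for p in priors])
        alphas = raw / raw.sum()
        lam = 0.5 if lam is None else lam
    else:
        lam = 1.0
    starts, contribs = [], []
    for i, seq in enumerate(seqs.seqs):
        best_j, best_v = None, -math.inf
        for j in range(len(seq) - k + 1):
            window = seq[j : j + k]
            if "N" in window:
                continue
            v = lam * score_word(pssm, window)
            for alpha, p in zip(alphas if priors else [], priors):
                v += (1 - lam) * alpha * math.log(max(p.rows[i][j], prob_floor))
            if v > best_v:  # strict: keeps the smallest argmax
                best_j, best_v = j, v
        starts.append(best_j)
        contribs.append(best_v)
    return starts, sum(contribs)


class TestAnnotate:
    def test_unique_best_base(self):
        seqs = SequenceSet(("x",), ("CCCCACCC",))
        ann = annotate(Motif("A"), seqs, delta=0.1)
        assert ann.starts == (4,)
        assert ann.strands == ("+",)
        assert ann.words == ("A",)

    def test_tie_broken_by_smallest_start(self):
        seqs = SequenceSet(("x",), ("AAAA",))
        ann = annotate(Motif("A"), seqs)
        assert ann.starts == (0,)

    def test_uniform_prior_does_not_move_annotations(self, rng):
        for _ in range(20):
            seqs = random_sequence_set(rng)
            k = int(rng.integers(1, 5))
            m = Motif("".join(rng.choice(list("ACGTRN"), size=k)))
            bare = annotate(m, seqs, delta=0.1)
            with_uniform = annotate(
                m, seqs, [uniform_prior(seqs, k)], lam=0.5, delta=0.1
            )
            for i, (a, b) in enumerate(zip(bare.starts, with_uniform.starts)):
                if a != b:
                    # only a mathematically tied pair may swap (the constant
                    # per-sequence shift can absorb a 1-ulp difference)
                    assert bare.contributions[i] == pytest.approx(
                        2 * with_uniform.contributions[i]
                        - math.log(1.0 / (seqs.lengths[i] - k + 1)),
                        rel=1e-12,
                    )

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            seqs = random_sequence_set(rng)
            k = int(rng.integers(1, 5))
            n_priors = int(rng.integers(0, 3))
            priors = [random_prior(rng, seqs, k, f"p{p}") for p in range(n_priors)]
            lam = float(rng.uniform(0.1, 1.0)) if priors else None
            m = Motif("".join(rng.choice(list("ACGTRYSWKMBDHVN"), size=k)))
            ann = annotate(m, seqs, priors, lam=lam, delta=0.1)
            starts, total = brute_force_annotation(m, seqs, priors, lam, 0.1)
            assert list(ann.starts) == starts
            assert ann.total == pytest.approx(total)

    def test_windows_over_masked_bases_excluded(self):
        seqs = SequenceSet(("x",), ("ANAAAC",))
        ann = annotate(Motif("AA"), seqs)
        # starts 0 and 1 overlap the N; best admissible is 2
        assert ann.starts == (2,)

    def test_fully_masked_sequence_rejected(self):
        seqs = SequenceSet(("x", "y"), ("ACGTACGT", "ANNNA"))
        with pytest.raises(NoAdmissibleWindowError, match="y"):
            annotate(Motif("AA"), seqs)

    def test_contributions_non_positive(self, rng):
        for _ in range(10):
            seqs = random_sequence_set(rng)
            m = Motif("".join(rng.choice(list("ACGT"), size=2)))
            ann = annotate(m, seqs, delta=0.1)
            assert all(c <= 0 for c in ann.contributions)


class TestBis:
    def test_probability_one_motif_scores_zero(self):
        seqs = SequenceSet(("a", "b"), ("CCACGTCC", "ACGTGGGG"))
        assert bis(Motif("ACGT"), seqs, delta=0.0) == 0.0

    def test_hand_computed_prior_balance(self):
        seqs = SequenceSet(("a",), ("AC",))
        prior = Prior("p", (np.array([0.8, 0.2]),))
        value = bis(Motif("A"), seqs, [prior], lam=0.5, delta=0.1)
        assert value == pytest.approx(0.5 * math.log(0.9) + 0.5 * math.log(0.8))
        ann = annotate(Motif("A"), seqs, [prior], lam=0.5, delta=0.1)
        assert ann.starts == (0,)

    def test_non_positive_on_random_instances(self, rng):
        for _ in range(100):
            seqs = random_sequence_set(rng)
            k = int(rng.integers(1, 5))
            priors = [random_prior(rng, seqs, k)] if rng.random() < 0.5 else []
            m = Motif("".join(rng.choice(list("ACGTRYSWKMBDHVN"), size=k)))
            lam = float(rng.uniform(0.05, 1.0)) if priors else None
            delta = float(rng.choice([0.0, 0.05, 0.1, 0.5]))
            assert bis(m, seqs, priors, lam=lam, delta=delta) <= 0.0

    def test_monotone_in_prior_at_annotated_position(self, rng):
        seqs = SequenceSet(("a",), ("ACGTACGTAA",))
        m = Motif("ACGT")
        row = np.full(7, 0.1)
        prior = Prior("p", (row.copy(),))
        ann = annotate(m, seqs, [prior], lam=0.5, delta=0.1)
        j = ann.starts[0]
        base_value = bis(m, seqs, [prior], lam=0.5, delta=0.1)
        row[j] = 0.9
        boosted = bis(m, seqs, [Prior("p", (row,))], lam=0.5, delta=0.1)
        assert boosted >= base_value

    def test_lambda_one_ignores_priors(self, rng):
        seqs = random_sequence_set(rng)
        m = Motif("AC")
        prior = random_prior(rng, seqs, 2)
        assert bis(m, seqs, [prior], lam=1.0) == pytest.approx(bis(m, seqs))


class TestBisOf:
    def test_empty_motif_loses_to_any_real_motif(self, rng):
        seqs = random_sequence_set(rng)
        m = Motif("AC")
        assert bis_of(m, seqs) > bis_of(EMPTY_MOTIF)

    def test_empty_motif_not_greater_than_itself(self):
        assert not bis_of(EMPTY_MOTIF) > bis_of(EMPTY_MOTIF)

    def test_ordering_consistent_with_bis(self, rng):
        seqs = random_sequence_set(rng, n_max=3)
        motifs = [Motif("".join(rng.choice(list("ACGTRN"), size=2))) for _ in range(5)]
        scores = [bis(m, seqs) for m in motifs]
        vias = [bis_of(m, seqs) for m in motifs]
        assert scores == vias


class TestBothStrands:
    def test_reverse_occurrence_found_on_minus_strand(self):
        # ACGGT present only as reverse complement (ACCGT) on the minus strand
        seqs = SequenceSet(("x",), ("TTACCGTTTT",))
        ann_fwd = annotate(Motif("ACGGT"), seqs, delta=0.1)
        ann_both = annotate(Motif("ACGGT"), seqs, delta=0.1, both_strands=True)
        assert ann_both.strands == ("-",)
        assert ann_both.contributions[0] > ann_fwd.contributions[0]
        assert ann_both.starts == (2,)

    def test_both_strands_never_scores_worse(self, rng):
        for _ in range(10):
            seqs = random_sequence_set(rng)
            m = Motif("".join(rng.choice(list("ACGT"), size=3)))
            assert bis(m, seqs, both_strands=True) >= bis(m, seqs) - 1e-12
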