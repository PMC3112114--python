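"""The balanced information score (BIS): per-sequence annotation and the
global objective.

For a candidate IUPAC motif ``m`` with induced PSSM probability ``P_m``, the
score over sequences ``f_1..f_N`` with priors ``S_1..S_l`` (convex weights
``alpha_p``) and balance constant ``lambda`` is

    BIS(m) = sum_i max_j [ lambda * log P_m(f_i[j..j+k-1])
                           + (1 - lambda) * sum_p alpha_p * log S_p[i, j] ]

i.e. minus the lambda-balanced self-information of observing the motif and
the priors at the annotated (per-sequence argmax) positions.  Both factors
are probabilities, so every term is <= 0 and the score is upper-bounded by 0;
it is 0 exactly when the motif occurs with probability 1 in every sequence
(and, if lambda < 1, the priors put probability 1 on the annotated starts).

With no priors, lambda plays no role and the score reduces to minus the
self-information of the annotated occurrences alone.

Windows overlapping a masked (N) base are never annotation candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    EMPTY_MOTIF,
    BASE_INDEX,
    SIGMA,
    SYMBOL_INDEX,
    Config,
    EmptyMotif,
    Motif,
    SequenceSet,
    symbol_probability_table,
)
from .priors import Prior, normalize_weights

__all__ = ["Annotation", "BisScorer", "annotate", "bis", "bis_of", "NoAdmissibleWindowError"]


class NoAdmissibleWindowError(ValueError):
    """A sequence offers no window free of masked bases."""


@dataclass(frozen=True)
class Annotation:
    """Chosen motif start per sequence, with the per-sequence balanced term."""

    starts: tuple[int, ...]
    strands: tuple[str, ...]
    contributions: tuple[float, ...]
    words: tuple[str, ...]

    @property
    def total(self) -> float:
        return float(sum(self.contributions))

    def to_tsv(self, path: str | Path, seqs: SequenceSet) -> None:
        with open(path, "w") as fh:
            fh.write("sequence_id\tstart\tstrand\tword\tcontribution\n")
            for sid, j, st, w, c in zip(
                seqs.ids, self.starts, self.strands, self.words, self.contributions
            ):
                fh.write(f"{sid}\t{j}\t{st}\t{w}\t{c:.6f}\n")

    def to_bed(self, path: str | Path, seqs: SequenceSet, k: int, name: str = "motif") -> None:
        """BED6 (0-based half-open); score column maps the contribution to 0-1000."""
        contribs = np.asarray(self.contributions)
        lo = contribs.min()
        span = contribs.max() - lo
        with open(path, "w") as fh:
            for sid, j, st, c in zip(seqs.ids, self.starts, self.strands, contribs):
                score = 1000 if span == 0 else int(round(1000 * (c - lo) / span))
                fh.write(f"{sid}\t{j}\t{j + k}\t{name}\t{score}\t{st}\n")


class BisScorer:
    """Precomputed scoring context for one (sequences, priors, k) instance.

    Builds the window base-index matrices and the motif-independent prior
    log term once, so that evaluating a motif (or a single-position
    substitution, via :meth:`column_cache`) is a handful of vectorised
    gathers and a segmented max.
    """

    def __init__(
        self,
        seqs: SequenceSet,
        k: int,
        priors: Sequence[Prior] = (),
        lam: float | None = None,
        delta: float = 0.1,
        both_strands: bool = False,
        prob_floor: float = 1e-10,
    ):
        seqs.require_min_length(k)
        self.seqs = seqs
        self.k = k
        self.priors = tuple(priors)
        self.lam = 1.0 if not priors else (0.5 if lam is None else lam)
        if not 0.0 < self.lam <= 1.0:
            raise ValueError(f"lambda must lie in (0, 1], got {lam}")
        self.delta = delta
        self.both_strands = both_strands
        for p in self.priors:
            p.validate_against(seqs, k)
        with np.errstate(divide="ignore"):
            self._log15 = np.log(symbol_probability_table(delta))  # (15, 4)

        enc = seqs.encoded()
        windows = []
        offsets = [0]
        for arr in enc:
            w = np.lib.stride_tricks.sliding_window_view(arr, k)
            windows.append(w)
            offsets.append(offsets[-1] + w.shape[0])
        self._win = np.ascontiguousarray(np.vstack(windows))  # (W_total, k), int8
        self._starts = np.asarray(offsets[:-1])
        self._offsets = np.asarray(offsets)
        self._n_win = self._win.shape[0]
        admissible = ~(self._win >= 4).any(axis=1)
        for i, sid in enumerate(seqs.ids):
            lo, hi = self._offsets[i], self._offsets[i + 1]
            if not admissible[lo:hi].any():
                raise NoAdmissibleWindowError(
                    f"sequence {sid!r} has no window of width {k} free of masked bases"
                )
        # scoring gathers index a 4-wide table; masked windows are excluded
        # through the -inf prior term, so clipping their codes is safe
        self._win_score = np.minimum(self._win, 3)
        # reverse-strand view: complement bases read right-to-left
        if both_strands:
            self._win_rev = np.ascontiguousarray(3 - self._win_score[:, ::-1])
        else:
            self._win_rev = None

        # motif-independent additive term: (1-lam) * sum_p alpha_p log S_p,
        # with -inf baked in at inadmissible windows
        base = np.zeros(self._n_win)
        if self.priors and self.lam < 1.0:
            alphas = normalize_weights([p.weight for p in self.priors])
            for alpha, p in zip(alphas, self.priors):
                logs = np.concatenate(
                    [np.log(np.maximum(row, prob_floor)) for row in p.rows]
                )
                base += alpha * logs
            base *= 1.0 - self.lam
        base[~admissible] = -np.inf
        self._prior_term = base
        self.alphas = (
            normalize_weights([p.weight for p in self.priors]) if self.priors else np.array([])
        )
        self._col_cache: dict[int, np.ndarray] = {}

    # -- motif evaluation ---------------------------------------------------

    def _codes(self, m: Motif) -> list[int]:
        if m.width != self.k:
            raise ValueError(f"motif width {m.width} != scorer k {self.k}")
        return [SYMBOL_INDEX[s] for s in m.symbols]

    def _window_logprobs(self, m: Motif, win: np.ndarray) -> np.ndarray:
        L = self._log15[self._codes(m)]  # (k, 4)
        with np.errstate(invalid="ignore"):
            return L[np.arange(self.k)[None, :], win].sum(axis=1)

    def combined_scores(self, m: Motif) -> np.ndarray:
        """Per-window balanced score, shape (S, W) with S strands."""
        fwd = self.lam * self._window_logprobs(m, self._win_score) + self._prior_term
        if self._win_rev is None:
            return fwd[None, :]
        rev = self.lam * self._window_logprobs(m, self._win_rev) + self._prior_term
        return np.stack([fwd, rev])

    def column_cache(self, i: int) -> np.ndarray:
        """lambda-scaled log contribution of every symbol at motif position i.

        Shape (S, 15, W); candidate scores for a substitution at position i
        are ``T - cache[:, old] + cache[:, new]``.  Motif-independent, so it
        is memoised and shared across all refinements on this instance.
        """
        cached = self._col_cache.get(i)
        if cached is not None:
            return cached
        mats = (
            [self._win_score]
            if self._win_rev is None
            else [self._win_score, self._win_rev]
        )
        out = np.empty((len(mats), 15, self._n_win))
        for s, mat in enumerate(mats):
            out[s] = self.lam * self._log15[:, mat[:, i]]
        self._col_cache[i] = out
        return out

    def total_from_scores(self, scores: np.ndarray) -> float:
        """Sum over sequences of the max per-window (and per-strand) score."""
        best = scores.max(axis=0) if scores.shape[0] > 1 else scores[0]
        with np.errstate(invalid="ignore"):
            per_seq = np.maximum.reduceat(best, self._starts)
        return float(per_seq.sum())

    def bis(self, m: Motif) -> float:
        """The balanced information score of ``m`` (always <= 0)."""
        return self.total_from_scores(self.combined_scores(m))

    def annotate(self, m: Motif) -> Annotation:
        """Argmax start per sequence; ties broken by smallest j, then + strand."""
        scores = self.combined_scores(m)
        starts, strands, contribs, words = [], [], [], []
        for i, seq in enumerate(self.seqs.seqs):
            lo, hi = self._offsets[i], self._offsets[i + 1]
            block = scores[:, lo:hi]  # (S, w_i)
            flat_best = block.max(axis=0)
            j = int(np.argmax(flat_best))  # first max = smallest start
            strand = "+"
            if block.shape[0] > 1 and block[1, j] > block[0, j]:
                strand = "-"
            starts.append(j)
            strands.append(strand)
            contribs.append(float(flat_best[j]))
            words.append(seq[j : j + self.k])
        return Annotation(tuple(starts), tuple(strands), tuple(contribs), tuple(words))


def annotate(
    m: Motif,
    seqs: SequenceSet,
    priors: Sequence[Prior] = (),
    lam: float | None = None,
    delta: float = 0.1,
    both_strands: bool = False,
) -> Annotation:
    """Annotate the best-scoring motif start in every sequence."""
    return BisScorer(seqs, m.width, priors, lam, delta, both_strands).annotate(m)


def bis(
    m: Motif,
    seqs: SequenceSet,
    priors: Sequence[Prior] = (),
    lam: float | None = None,
    delta: float = 0.1,
    both_strands: bool = False,
) -> float:
    """Balanced information score of ``m`` over ``seqs`` with ``priors``."""
    return BisScorer(seqs, m.width, priors, lam, delta, both_strands).bis(m)


def bis_of(
    x: Motif | EmptyMotif,
    seqs: SequenceSet | None = None,
    priors: Sequence[Prior] = (),
    lam: float | None = None,
    delta: float = 0.1,
    both_strands: bool = False,
) -> float:
    """Score of a motif or of the empty-motif sentinel (which scores -inf)."""
    if isinstance(x, EmptyMotif):
        return -math.inf
    if seqs is None:
        raise ValueError("sequences required to score a real motif")
    return bis(x, seqs, priors, lam, delta, both_strands)
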