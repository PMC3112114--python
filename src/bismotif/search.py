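"""Greedy IUPAC refinement and the seeded discovery driver.

``greedy_refine`` hill-climbs a single motif: positions are visited in a
circular order and at each position every IUPAC symbol is tried; a
substitution is kept only when it strictly increases the balanced
information score.  The search stops once k consecutive positions pass
without any accepted substitution, i.e. the motif survived a complete
unchanged round and no single-position substitution improves it.  Because
every accepted move strictly increases a score that is upper-bounded by 0
and the motif space is finite, the procedure terminates and never revisits
a motif.

Strict improvement is epsilon-guarded: a substitution (or a later seed in
the driver) wins only when it beats the incumbent by more than a relative
tolerance of 1e-9.  Mathematically tied alternatives can differ by a few
ulps depending on summation order — e.g. the same objective evaluated with
and without a uniform prior, which shifts every score by a constant — and a
plain ``>`` would let that rounding noise pick different tie members on
different runs.  Genuine score improvements in this objective are many
orders of magnitude larger than the guard.

``discover`` drives the whole pipeline: enumerate over-represented seed
words (or take caller-supplied ones), refine the top z seeds, and report
the refined motif with the strictly highest score (first encountered wins
on ties).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    EMPTY_MOTIF,
    SIGMA,
    Config,
    DNA_BASES,
    Motif,
    iupac_to_pssm,
)
from .core import SequenceSet
from .priors import Prior
from .scoring import Annotation, BisScorer
from .seeder import SeedCandidate, SeederParams, enumerate_seeds

__all__ = ["SearchTrace", "Move", "DiscoveryResult", "greedy_refine", "discover", "NoSeedsError"]


class NoSeedsError(RuntimeError):
    """The seeder produced no starting points."""


def _improves(candidate: float, incumbent: float) -> bool:
    """Strictly better, beyond float tie noise (relative 1e-9 guard)."""
    if incumbent == -math.inf:
        return candidate > -math.inf
    return candidate > incumbent + 1e-9 * (1.0 + abs(incumbent))


@dataclass(frozen=True)
class Move:
    position: int
    old: str
    new: str
    score_before: float
    score_after: float


@dataclass(frozen=True)
class SearchTrace:
    """Accepted substitutions and the number of inner-loop evaluations."""

    accepted_moves: tuple[Move, ...]
    iterations: int

    def motifs_visited(self, m0: Motif) -> list[Motif]:
        """The chain of motifs after each accepted move, starting from m0."""
        chain = [m0]
        m = m0
        for mv in self.accepted_moves:
            m = m.substitute(mv.position, mv.new)
            chain.append(m)
        return chain


def _degenerate_ok(m: Motif, i: int, alpha: str, max_degenerate: int | None) -> bool:
    if max_degenerate is None:
        return True
    count = m.degenerate_count
    if m.symbols[i] not in DNA_BASES:
        count -= 1
    if alpha not in DNA_BASES:
        count += 1
    return count <= max_degenerate


def greedy_refine(
    m0: Motif,
    scorer: BisScorer,
    max_degenerate: int | None = None,
) -> tuple[Motif, SearchTrace]:
    """Refine ``m0`` by circular single-position IUPAC substitution hill-climbing.

    Returns the locally optimal motif and its search trace.  A substitution
    introducing degeneracy is admissible only while the motif's degenerate
    position count stays within ``max_degenerate`` (None = unlimited).
    """
    k = scorer.k
    if m0.width != k:
        raise ValueError(f"seed width {m0.width} != configured k {k}")
    m = m0
    scores = scorer.combined_scores(m)
    cur = scorer.total_from_scores(scores)
    incremental = scorer.delta > 0.0  # -inf columns break incremental deltas
    moves: list[Move] = []
    evals = 0
    t = 0
    i = 0
    while t < k:
        changed = False
        # symbol-column contributions at position i are motif-independent
        cache = scorer.column_cache(i) if incremental else None
        for alpha in SIGMA:
            if alpha == m.symbols[i]:
                continue  # identity substitution can never strictly improve
            if not _degenerate_ok(m, i, alpha, max_degenerate):
                continue
            evals += 1
            if incremental:
                old_idx = SIGMA.index(m.symbols[i])
                new_idx = SIGMA.index(alpha)
                cand = scorer.total_from_scores(
                    scores - cache[:, old_idx] + cache[:, new_idx]
                )
            else:
                cand = scorer.total_from_scores(
                    scorer.combined_scores(m.substitute(i, alpha))
                )
            if _improves(cand, cur):
                old_sym = m.symbols[i]
                new_m = m.substitute(i, alpha)
                # confirm with a from-scratch evaluation so float drift from
                # the incremental path never enters the accepted chain
                fresh_scores = scorer.combined_scores(new_m)
                fresh = scorer.total_from_scores(fresh_scores)
                if _improves(fresh, cur):
                    moves.append(Move(i, old_sym, alpha, cur, fresh))
                    m = new_m
                    scores = fresh_scores
                    cur = fresh
                    t = 0
                    changed = True
        if not changed:
            t += 1
        i = (i + 1) % k
    return m, SearchTrace(tuple(moves), evals)


@dataclass(frozen=True)
class DiscoveryResult:
    """Everything a discovery run reports."""

    motif: Motif
    score: float
    annotation: Annotation
    seeds: tuple[str, ...]
    seed_candidates: tuple[SeedCandidate, ...]
    traces: tuple[SearchTrace, ...]
    refined: tuple[tuple[str, float], ...]  # (refined motif, score) per seed
    config: Config
    lam: float

    def report_dict(self, verbose: bool = False) -> dict:
        pssm = iupac_to_pssm(self.motif, self.config.delta)
        out = {
            "motif": self.motif.symbols,
            "bis": self.score,
            "lambda": self.lam,
            "k": self.config.k,
            "delta": self.config.delta,
            "pssm": [[round(v, 6) for v in row] for row in pssm.matrix.tolist()],
            "seeds": list(self.seeds),
            "refined": [{"motif": m, "bis": s} for m, s in self.refined],
            "annotations": [
                {"start": j, "strand": st, "word": w, "contribution": c}
                for j, st, w, c in zip(
                    self.annotation.starts,
                    self.annotation.strands,
                    self.annotation.words,
                    self.annotation.contributions,
                )
            ],
        }
        if verbose:
            out["traces"] = [
                {
                    "iterations": tr.iterations,
                    "moves": [
                        {
                            "position": mv.position,
                            "old": mv.old,
                            "new": mv.new,
                            "before": mv.score_before,
                            "after": mv.score_after,
                        }
                        for mv in tr.accepted_moves
                    ],
                }
                for tr in self.traces
            ]
        return out

    def report_text(self) -> str:
        pssm = iupac_to_pssm(self.motif, self.config.delta)
        lines = [
            f"motif\t{self.motif.symbols}",
            f"bis\t{self.score:.6f}",
            f"lambda\t{self.lam}",
            f"k\t{self.config.k}",
            "pssm (rows A,C,G,T):",
        ]
        for base, row in zip("ACGT", pssm.matrix):
            lines.append(base + "\t" + "\t".join(f"{v:.4f}" for v in row))
        lines.append("matrix (minimal motif-matrix format, columns = positions):")
        lines.append(f">{self.motif.symbols}")
        for row in pssm.matrix.T:
            lines.append("\t".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def discover(
    seqs: SequenceSet,
    priors: Sequence[Prior] = (),
    config: Config | None = None,
    seeds: Sequence[str] | None = None,
) -> DiscoveryResult:
    """Run seeded greedy motif discovery end to end.

    ``seeds`` bypasses the enumerator (any external tool can supply starting
    words); otherwise the seeder's ranked list is used and the top ``z``
    words are refined.  Returns the refined motif with the strictly highest
    balanced information score.
    """
    config = config or Config()
    seqs.require_min_length(config.k)
    candidates: tuple[SeedCandidate, ...] = ()
    if seeds is None:
        params = SeederParams(
            k=config.k,
            e=config.e,
            quorum_count=max(1, math.ceil(config.quorum_frac * seqs.n_sequences)),
            z_min=config.z_min,
            z_max=config.z_max,
        )
        candidates = tuple(enumerate_seeds(seqs, params))
        seed_words = [c.word for c in candidates[: config.z]]
    else:
        seed_words = [w.upper() for w in seeds][: config.z]
        for w in seed_words:
            if len(w) != config.k or set(w) - set(DNA_BASES):
                raise ValueError(f"seed {w!r} is not a width-{config.k} DNA word")
    if not seed_words:
        raise NoSeedsError(
            "seeder returned no candidate words; loosen the seeder parameters "
            "(larger e, smaller quorum) or supply a seeds file"
        )

    scorer = BisScorer(
        seqs,
        config.k,
        priors,
        config.lam,
        config.delta,
        config.both_strands,
        config.prob_floor,
    )
    best: Motif | None = None
    best_score = -math.inf  # the empty motif's sentinel score
    traces = []
    refined = []
    for word in seed_words:
        m, trace = greedy_refine(Motif(word), scorer, config.max_degenerate)
        s = scorer.bis(m)
        traces.append(trace)
        refined.append((m.symbols, s))
        if _improves(s, best_score):
            best = m
            best_score = s
    if best is None or not math.isfinite(best_score):
        raise NoSeedsError(
            "no seed achieved a finite score (delta=0 with no compatible "
            "occurrence anywhere); increase delta or check the input"
        )
    return DiscoveryResult(
        motif=best,
        score=best_score,
        annotation=scorer.annotate(best),
        seeds=tuple(seed_words),
        seed_candidates=candidates,
        traces=tuple(traces),
        refined=tuple(refined),
        config=config,
        lam=scorer.lam,
    )
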