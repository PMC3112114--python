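"""Combinatorial enumeration of over-represented width-k consensus words.

Candidate words are grown letter by letter over {A,C,G,T}; a prefix is
pruned as soon as the number of sequences containing it (any window whose
first ``|prefix|`` bases lie within Hamming distance ``e`` of the prefix)
falls below the quorum.  Because the Hamming distance of a prefix never
exceeds the distance of the full word, this prunes no word that would meet
the quorum at full width.  Full-length survivors are ranked by a z-score of
their support against a uniform-background null.

This is a deliberately simple exhaustive enumerator standing where a
suffix-tree consensus extractor (SMILE / RISO / RISOTTO / Weeder style)
would normally sit; any such tool can replace it by feeding its words to
the discovery driver through a seeds file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .core import DNA_BASES, ConfigError, FormatError, SequenceSet

__all__ = [
    "SeederParams",
    "SeedCandidate",
    "hamming",
    "enumerate_seeds",
    "significance",
    "sequence_hit_probability",
    "neighborhood_size",
    "read_seeds",
]


@dataclass(frozen=True)
class SeederParams:
    """Enumeration parameters.

    ``e`` is the mismatch budget for an occurrence; ``quorum_count`` the
    minimum number of sequences that must contain one; ``z_min``/``z_max``
    bound how many ranked words are returned (the quorum is relaxed in steps
    of ceil(0.05 N) until at least ``z_min`` words survive or it reaches 1).
    """

    k: int
    e: int = 2
    quorum_count: int | None = None  # None -> ceil(0.8 N), resolved at run time
    z_min: int = 10
    z_max: int = 50

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if self.e < 0:
            raise ConfigError(f"e must be >= 0, got {self.e}")
        if self.quorum_count is not None and self.quorum_count < 1:
            raise ConfigError(f"quorum_count must be >= 1, got {self.quorum_count}")
        if not 1 <= self.z_min <= self.z_max:
            raise ConfigError(
                f"need 1 <= z_min <= z_max, got z_min={self.z_min}, z_max={self.z_max}"
            )


@dataclass(frozen=True)
class SeedCandidate:
    """A surviving width-k DNA word with its support and ranking score."""

    word: str
    support: int
    significance: float


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length words."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y)


def neighborhood_size(k: int, e: int) -> int:
    """Number of width-k DNA words within Hamming distance e of a fixed word."""
    return sum(math.comb(k, d) * 3**d for d in range(min(e, k) + 1))


def sequence_hit_probability(k: int, e: int, n: int) -> float:
    """P(>= 1 window within distance e of a fixed word) in an i.i.d. uniform
    random sequence of length n, treating windows as independent trials."""
    w = n - k + 1
    if w <= 0:
        return 0.0
    p_word = min(1.0, neighborhood_size(k, e) / 4**k)
    return 1.0 - (1.0 - p_word) ** w


def significance(support: int, k: int, e: int, lengths: Sequence[int]) -> float:
    """z-score of the observed support against the uniform-background null.

    The null depends only on (k, e, sequence lengths), so equally supported
    words on the same instance always tie.
    """
    probs = np.array([sequence_hit_probability(k, e, n) for n in lengths])
    mu = probs.sum()
    var = (probs * (1.0 - probs)).sum()
    if var <= 0.0:
        if support == round(mu):
            return 0.0
        return math.inf if support > mu else -math.inf
    return float((support - mu) / math.sqrt(var))


def _admissible_windows(seqs: SequenceSet, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Stacked admissible window matrix (W, k) and the owning sequence index."""
    mats, owners = [], []
    for i, arr in enumerate(seqs.encoded()):
        if arr.size < k:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, k)
        keep = ~(win >= 4).any(axis=1)
        win = win[keep]
        mats.append(win)
        owners.append(np.full(win.shape[0], i, dtype=np.int32))
    if not mats:
        return np.empty((0, k), dtype=np.int8), np.empty(0, dtype=np.int32)
    return np.ascontiguousarray(np.vstack(mats)), np.concatenate(owners)


def _dense_supports(
    win: np.ndarray, owner: np.ndarray, n_seqs: int, k: int, e: int
) -> np.ndarray:
    """Support of every width-k word at once, for small e and word spaces.

    Every word within distance e of a window is reachable by rewriting some
    size-min(e,k) position subset of that window with arbitrary bases, so
    scattering all those rewrites into a (word, sequence) presence table
    counts exactly the within-distance-e supports the extension search
    counts (duplicate rewrites collapse in the boolean table).
    """
    from itertools import combinations, product

    pow4 = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    word_int = win.astype(np.int64) @ pow4
    present = np.zeros((4**k) * n_seqs, dtype=bool)
    r = min(e, k)
    for subset in combinations(range(k), r):
        stripped = word_int.copy()
        for t in subset:
            stripped -= win[:, t].astype(np.int64) * pow4[t]
        base_idx = stripped * n_seqs + owner
        for vals in product(range(4), repeat=r):
            offset = sum(v * pow4[t] for t, v in zip(subset, vals)) * n_seqs
            present[base_idx + offset] = True
    return present.reshape(4**k, n_seqs).sum(axis=1)


def _decode_word(word_int: int, k: int) -> str:
    out = []
    for t in range(k):
        out.append(DNA_BASES[(word_int >> (2 * (k - 1 - t))) & 3])
    return "".join(out)


def _enumerate_at_quorum(
    win: np.ndarray,
    owner: np.ndarray,
    n_seqs: int,
    k: int,
    e: int,
    quorum: int,
) -> list[tuple[str, int]]:
    """Depth-first extension with quorum pruning; returns (word, support)."""
    results: list[tuple[str, int]] = []
    if win.shape[0] == 0:
        return results

    def support_of(idx: np.ndarray) -> int:
        return int(np.bincount(owner[idx], minlength=n_seqs).astype(bool).sum())

    def recurse(prefix: str, idx: np.ndarray, mism: np.ndarray) -> None:
        depth = len(prefix)
        if depth == k:
            results.append((prefix, support_of(idx)))
            return
        col = win[idx, depth]
        for b, base in enumerate(DNA_BASES):
            new_mism = mism + (col != b)
            keep = new_mism <= e
            sub = idx[keep]
            if sub.size == 0:
                continue
            if support_of(sub) < quorum:
                continue
            recurse(prefix + base, sub, new_mism[keep])

    recurse("", np.arange(win.shape[0]), np.zeros(win.shape[0], dtype=np.int16))
    return results


def enumerate_seeds(
    seqs: SequenceSet, params: SeederParams, method: str = "auto"
) -> list[SeedCandidate]:
    """Ranked over-represented width-k words.

    Order: significance descending, then support descending, then word
    lexicographic; truncated to ``z_max``.  If fewer than ``z_min`` words
    survive, the quorum is relaxed by ceil(0.05 N) steps down to 1.

    ``method``: "dfs" forces the pruned extension search, "dense" the
    all-words support table (small e only); "auto" picks dense whenever the
    table fits, as both count identical supports.
    """
    k, e = params.k, params.e
    if k > min(seqs.lengths):
        raise ConfigError(
            f"k={k} exceeds the shortest sequence length {min(seqs.lengths)}"
        )
    n = seqs.n_sequences
    quorum = params.quorum_count if params.quorum_count is not None else math.ceil(0.8 * n)
    quorum = min(max(1, quorum), n)
    win, owner = _admissible_windows(seqs, k)
    step = max(1, math.ceil(0.05 * n))
    r = min(e, k)
    dense_ok = (4**k) * n <= 64_000_000 and math.comb(k, r) * 4**r <= 4096
    if method == "dense" and not dense_ok:
        raise ConfigError("dense enumeration infeasible for this (k, e, N)")
    use_dense = dense_ok if method == "auto" else method == "dense"

    if use_dense:
        supports = _dense_supports(win, owner, n, k, e)
        while True:
            hits = np.nonzero(supports >= quorum)[0]
            if hits.size >= params.z_min or quorum == 1:
                break
            quorum = max(1, quorum - step)
        # significance is strictly increasing in support on a fixed instance
        # and word_int order equals lexicographic order (A<C<G<T), so rank
        # numerically and decode only the survivors
        sup = supports[hits]
        order = np.lexsort((hits, -sup))[: params.z_max]
        found = [(_decode_word(int(hits[i]), k), int(sup[i])) for i in order]
    else:
        while True:
            found = _enumerate_at_quorum(win, owner, n, k, e, quorum)
            if len(found) >= params.z_min or quorum == 1:
                break
            quorum = max(1, quorum - step)
        found.sort(key=lambda ws: (-ws[1], ws[0]))
        found = found[: params.z_max]
    z_by_support = {s: significance(s, k, e, seqs.lengths) for s in {s for _, s in found}}
    return [SeedCandidate(word, s, z_by_support[s]) for word, s in found]


def read_seeds(path: str | Path, k: int) -> list[str]:
    """Read a seeds file: one width-k DNA word per line (external enumerators
    can supply starting points through this)."""
    words = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        word = line.strip().upper()
        if not word or word.startswith("#"):
            continue
        if len(word) != k or set(word) - set(DNA_BASES):
            raise FormatError(
                f"{path}:{lineno}: {word!r} is not a width-{k} word over A,C,G,T"
            )
        words.append(word)
    return words
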