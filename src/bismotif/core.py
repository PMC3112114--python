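"""Core domain types: IUPAC motifs, PSSMs, sequence sets and run configuration.

A motif is a fixed-width string over the 15-letter IUPAC nucleotide alphabet.
It induces a 4xk column-stochastic position-specific scoring matrix (PSSM):
within each column the bases belonging to the IUPAC symbol's base set share
probability mass ``1 - delta`` uniformly, the remaining bases share ``delta``
uniformly.  ``delta = 0`` gives exact-match semantics (zero probability off the
consensus set); the default ``delta = 0.1`` keeps every log-probability finite
so that the information score stays defined on sequences where the motif has
no exact-compatible occurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "SIGMA",
    "IUPAC_SETS",
    "DNA_BASES",
    "Motif",
    "EmptyMotif",
    "EMPTY_MOTIF",
    "PSSM",
    "SequenceSet",
    "Config",
    "InvalidMotifError",
    "ConfigError",
    "FormatError",
    "AlignmentError",
    "iupac_to_pssm",
    "score_word",
    "substitute",
    "pssm_distance",
    "reverse_complement",
]

DNA_BASES = "ACGT"

#: Canonical symbol order; also the fixed scan order of the greedy search.
SIGMA = "ACGTRYSWKMBDHVN"

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: IUPAC complement (base-set complement of each symbol's set).
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
SYMBOL_INDEX = {s: i for i, s in enumerate(SIGMA)}


class InvalidMotifError(ValueError):
    """A motif string contains a character outside the IUPAC alphabet."""


class ConfigError(ValueError):
    """A configuration value violates its domain constraint."""


class FormatError(ValueError):
    """An input file violates its declared format."""


class AlignmentError(ValueError):
    """A prior or peak file does not align with the sequence set."""


@dataclass(frozen=True)
class Motif:
    """A fixed-width IUPAC consensus string, the unit the greedy search mutates."""

    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise InvalidMotifError("motif must have width >= 1")
        bad = set(self.symbols) - set(SIGMA)
        if bad:
            raise InvalidMotifError(
                f"non-IUPAC character(s) {sorted(bad)!r} in motif {self.symbols!r}"
            )

    @property
    def width(self) -> int:
        return len(self.symbols)

    @property
    def degenerate_count(self) -> int:
        """Number of positions holding a symbol outside {A,C,G,T}."""
        return sum(1 for s in self.symbols if s not in DNA_BASES)

    def substitute(self, i: int, alpha: str) -> "Motif":
        return substitute(self, i, alpha)

    def reverse_complement(self) -> "Motif":
        return Motif("".join(IUPAC_COMPLEMENT[s] for s in reversed(self.symbols)))

    def __str__(self) -> str:
        return self.symbols


class EmptyMotif:
    """Sentinel whose score compares strictly below any real motif's score.

    Used to initialise the discovery driver's running best; it is never part
    of a reported result.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "EmptyMotif()"


EMPTY_MOTIF = EmptyMotif()


def substitute(m: Motif, i: int, alpha: str) -> Motif:
    """Return ``m`` with position ``i`` (0-based) replaced by symbol ``alpha``."""
    if not 0 <= i < m.width:
        raise IndexError(f"position {i} out of range for width-{m.width} motif")
    if alpha not in IUPAC_SETS:
        raise InvalidMotifError(f"{alpha!r} is not an IUPAC symbol")
    return Motif(m.symbols[:i] + alpha + m.symbols[i + 1 :])


def reverse_complement(word: str) -> str:
    """Reverse complement of a plain or IUPAC DNA string."""
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(word))


def _symbol_column(symbol: str, delta: float) -> np.ndarray:
    members = IUPAC_SETS[symbol]
    col = np.empty(4)
    n_in = len(members)
    if n_in == 4:
        col[:] = 0.25
        return col
    for base, idx in zip(DNA_BASES, range(4)):
        if base in members:
            col[idx] = (1.0 - delta) / n_in
        else:
            col[idx] = delta / (4 - n_in)
    return col


def symbol_probability_table(delta: float) -> np.ndarray:
    """(15, 4) matrix of base probabilities for every IUPAC symbol at ``delta``."""
    if not 0.0 <= delta < 1.0:
        raise ConfigError(f"smoothing delta must be in [0, 1), got {delta}")
    return np.stack([_symbol_column(s, delta) for s in SIGMA])


@dataclass(frozen=True)
class PSSM:
    """Column-stochastic 4 x k matrix induced from an IUPAC motif.

    Rows are ordered A, C, G, T.  ``smoothing`` records the delta used to
    assign off-consensus mass.
    """

    matrix: np.ndarray  # shape (4, k)
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != 4:
            raise ValueError(f"PSSM matrix must be 4 x k, got shape {mat.shape}")
        if (mat < 0).any():
            raise ValueError("PSSM entries must be non-negative")
        sums = mat.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"PSSM columns must sum to 1, got {sums}")
        object.__setattr__(self, "matrix", mat)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_matrix(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.matrix)

    def reverse_complement(self) -> "PSSM":
        return PSSM(self.matrix[::-1, ::-1], self.smoothing)


def iupac_to_pssm(m: Motif | str, delta: float = 0.1) -> PSSM:
    """Translate an IUPAC motif into its smoothed PSSM.

    Bases in a symbol's set share probability ``1 - delta`` uniformly; bases
    outside share ``delta`` uniformly; a full {A,C,G,T} set gives the uniform
    column regardless of ``delta``.
    """
    if isinstance(m, str):
        m = Motif(m)
    table = symbol_probability_table(delta)
    cols = table[[SYMBOL_INDEX[s] for s in m.symbols]]
    return PSSM(cols.T, smoothing=delta)


def score_word(p: PSSM, w: str) -> float:
    """Log-probability of DNA word ``w`` under PSSM ``p`` (sum of column logs)."""
    if len(w) != p.width:
        raise ValueError(f"word length {len(w)} != PSSM width {p.width}")
    total = 0.0
    for j, base in enumerate(w):
        if base not in BASE_INDEX or base == "N":
            raise ValueError(f"word must be over A,C,G,T; got {base!r} at {j}")
        prob = p.matrix[BASE_INDEX[base], j]
        if prob == 0.0:
            return -math.inf
        total += math.log(prob)
    return total


def _distance_equal_width(a: np.ndarray, b: np.ndarray) -> float:
    col_dist = np.linalg.norm(a - b, axis=0)
    return float(col_dist.mean() / math.sqrt(2.0))


def pssm_distance(p: PSSM, q: PSSM, both_strands: bool = False) -> float:
    """Scaled Euclidean distance between two PSSMs, in [0, 1].

    Equal widths: per-column Euclidean distance, averaged over columns and
    divided by sqrt(2) (so identical matrices give 0 and disjoint point-mass
    matrices give 1).  Unequal widths: the shorter matrix slides over the
    longer and the minimum over all full-overlap offsets is reported.  With
    ``both_strands`` the reverse complement of ``q`` is also tried.
    """
    candidates = [q]
    if both_strands:
        candidates.append(q.reverse_complement())
    best = math.inf
    for qq in candidates:
        a, b = p.matrix, qq.matrix
        if a.shape[1] > b.shape[1]:
            a, b = b, a
        wa, wb = a.shape[1], b.shape[1]
        for off in range(wb - wa + 1):
            best = min(best, _distance_equal_width(a, b[:, off : off + wa]))
    return best


@dataclass(frozen=True)
class SequenceSet:
    """The N input DNA sequences with identifiers.

    Bases are upper-case A, C, G, T plus N for masked positions (windows
    overlapping a masked base are never annotation candidates).
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if not self.ids:
            raise ValueError("sequence set must contain at least one sequence")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence IDs must be unique")
        seqs = tuple(s.upper() for s in self.seqs)
        for sid, s in zip(self.ids, seqs):
            bad = set(s) - set("ACGTN")
            if bad:
                raise FormatError(
                    f"sequence {sid!r} contains non-DNA character(s) {sorted(bad)!r}"
                )
            if not s:
                raise FormatError(f"sequence {sid!r} is empty")
        object.__setattr__(self, "seqs", seqs)

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.seqs)

    def encoded(self) -> list[np.ndarray]:
        """Sequences as int8 arrays (A=0, C=1, G=2, T=3, N=4)."""
        lut = np.full(256, -1, dtype=np.int8)
        for base, idx in BASE_INDEX.items():
            lut[ord(base)] = idx
        return [
            lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)] for s in self.seqs
        ]

    def require_min_length(self, k: int) -> None:
        short = [sid for sid, n in zip(self.ids, self.lengths) if n < k]
        if short:
            raise FormatError(
                f"sequences shorter than motif width k={k}: {short[:5]}"
            )

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "SequenceSet":
        recs = list(records)
        return cls(tuple(r[0] for r in recs), tuple(r[1] for r in recs))

    @classmethod
    def from_fasta(cls, path: str | Path, min_length: int | None = None) -> "SequenceSet":
        """Read a FASTA file; IDs are the first whitespace-delimited header token."""
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise FormatError(f"no FASTA records found in {path}")
        ss = cls.from_records(records)
        if min_length is not None:
            ss.require_min_length(min_length)
        return ss

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for sid, s in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n")
                for off in range(0, len(s), width):
                    fh.write(s[off : off + width] + "\n")


@dataclass(frozen=True)
class Config:
    """Run configuration for discovery.

    ``lam`` balances sequence over-representation against prior information;
    ``None`` resolves to 1 when no priors are supplied and to 1/2 otherwise.
    ``weights`` are raw (unnormalised) prior weights; ``None`` means uniform.
    """

    k: int = 8
    lam: float | None = None
    weights: tuple[float, ...] | None = None
    z: int = 10
    z_min: int = 10
    z_max: int = 50
    e: int = 2
    quorum_frac: float = 0.8
    max_degenerate: int | None = None
    prob_floor: float = 1e-10
    delta: float = 0.1
    both_strands: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError(f"motif width k must be >= 1, got {self.k}")
        if self.lam is not None and not 0.0 < self.lam <= 1.0:
            raise ConfigError(f"lambda must lie in (0, 1], got {self.lam}")
        if not 1 <= self.z <= self.z_max:
            raise ConfigError(f"need 1 <= z <= z_max, got z={self.z}, z_max={self.z_max}")
        if self.z_min > self.z_max:
            raise ConfigError(f"z_min={self.z_min} exceeds z_max={self.z_max}")
        if self.e < 0:
            raise ConfigError(f"mismatch budget e must be >= 0, got {self.e}")
        if not 0.0 < self.quorum_frac <= 1.0:
            raise ConfigError(f"quorum_frac must lie in (0, 1], got {self.quorum_frac}")
        if self.max_degenerate is not None and self.max_degenerate < 0:
            raise ConfigError("max_degenerate must be >= 0 or None")
        if not 0.0 < self.prob_floor < 1.0:
            raise ConfigError(f"prob_floor must lie in (0, 1), got {self.prob_floor}")
        if not 0.0 <= self.delta < 1.0:
            raise ConfigError(f"delta must lie in [0, 1), got {self.delta}")

    def resolved_lambda(self, n_priors: int) -> float:
        if n_priors == 0:
            return 1.0
        return 0.5 if self.lam is None else self.lam

    def with_overrides(self, **kwargs) -> "Config":
        return replace(self, **kwargs)
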