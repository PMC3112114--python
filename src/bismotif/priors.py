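"""Position-specific priors (PSPs): file I/O, validation and construction.

A PSP stores, for every sequence and every admissible motif start position,
the prior probability that a width-k motif starts there.  Priors come from
external evidence (orthologous conservation, duplex destabilisation energy,
nucleosome occupancy, ChIP-seq coverage); this module only loads, validates
and combines them, plus builds the two priors that need no external data:
the uniform prior and the peak-summit coverage prior.

File dialect (FASTA-like): a first comment line ``#k=<width>``, then for each
sequence a ``>`` header holding the sequence ID followed by exactly
``n_i - k + 1`` whitespace-separated probabilities in 0-based start order.

Entries are floored at ``prob_floor`` on load so their logarithms stay
finite; rows are deliberately NOT renormalised after flooring (the score only
ever compares entries within a sequence, and flooring preserves that order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import t as student_t

from .core import AlignmentError, ConfigError, FormatError, SequenceSet

__all__ = [
    "Prior",
    "PeakSpec",
    "read_psp",
    "write_psp",
    "read_peaks",
    "uniform_prior",
    "build_peak_psp",
    "normalize_weights",
    "DEFAULT_PROB_FLOOR",
]

DEFAULT_PROB_FLOOR = 1e-10


@dataclass(frozen=True)
class Prior:
    """One PSP: per sequence a probability vector over motif start positions."""

    name: str
    rows: tuple[np.ndarray, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError(f"prior {self.name!r} has no rows")
        rows = tuple(np.asarray(r, dtype=float) for r in self.rows)
        for i, row in enumerate(rows):
            if row.ndim != 1 or row.size == 0:
                raise FormatError(f"prior {self.name!r}: row {i} must be a non-empty vector")
            if (row < 0).any():
                raise FormatError(f"prior {self.name!r}: negative value in row {i}")
            if (row > 1).any():
                raise FormatError(f"prior {self.name!r}: value > 1 in row {i}")
        if self.weight < 0:
            raise ConfigError(f"prior weight must be >= 0, got {self.weight}")
        object.__setattr__(self, "rows", rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def floored(self, prob_floor: float = DEFAULT_PROB_FLOOR) -> "Prior":
        return Prior(
            self.name,
            tuple(np.maximum(r, prob_floor) for r in self.rows),
            self.weight,
        )

    def validate_against(self, seqs: SequenceSet, k: int) -> None:
        if self.n_rows != seqs.n_sequences:
            raise AlignmentError(
                f"prior {self.name!r} has {self.n_rows} rows for "
                f"{seqs.n_sequences} sequences"
            )
        for sid, n, row in zip(seqs.ids, seqs.lengths, self.rows):
            expected = n - k + 1
            if row.size != expected:
                raise FormatError(
                    f"prior {self.name!r}, sequence {sid!r}: row length "
                    f"{row.size} != n_i - k + 1 = {expected}"
                )


@dataclass(frozen=True)
class PeakSpec:
    """Peak-summit offsets per sequence, for the coverage-based prior.

    The summit is the highest-coverage position inside a ChIP-seq binding
    peak; ``step`` is the width of the constant steps (bp) and ``df`` the
    degrees of freedom of the Student t density that sets the step heights.
    """

    summits: dict[str, int]
    step: int = 25
    df: float = 3.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ConfigError(f"step must be > 0, got {self.step}")
        if self.df <= 0:
            raise ConfigError(f"df must be > 0, got {self.df}")
        if not self.summits:
            raise ConfigError("peak spec has no summits")

    def validate_against(self, seqs: SequenceSet) -> None:
        missing = [sid for sid in seqs.ids if sid not in self.summits]
        if missing:
            raise AlignmentError(f"no peak summit for sequence(s) {missing[:5]}")
        for sid, n in zip(seqs.ids, seqs.lengths):
            off = self.summits[sid]
            if not 0 <= off < n:
                raise AlignmentError(
                    f"summit offset {off} out of bounds for sequence {sid!r} (length {n})"
                )


def read_psp(
    path: str | Path,
    seqs: SequenceSet,
    k: int,
    prob_floor: float = DEFAULT_PROB_FLOOR,
    weight: float = 1.0,
) -> Prior:
    """Read and validate a PSP file against a sequence set.

    Rows are re-ordered to match ``seqs``; every sequence must be present and
    every row must have exactly ``n_i - k + 1`` entries.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines:
        raise FormatError(f"{path}: empty PSP file")
    pos = 0
    declared_k = None
    while pos < len(lines) and lines[pos].startswith("#"):
        stripped = lines[pos][1:].strip()
        if stripped.startswith("k="):
            declared_k = int(stripped[2:])
        pos += 1
    if declared_k is not None and declared_k != k:
        raise FormatError(f"{path}: declares k={declared_k} but run uses k={k}")
    rows: dict[str, np.ndarray] = {}
    current_id: str | None = None
    values: list[float] = []

    def flush() -> None:
        if current_id is None:
            return
        if current_id in rows:
            raise FormatError(f"{path}: duplicate sequence ID {current_id!r}")
        rows[current_id] = np.asarray(values, dtype=float)

    for line in lines[pos:]:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            current_id = line[1:].split()[0]
            values = []
        else:
            if current_id is None:
                raise FormatError(f"{path}: probability data before any '>' header")
            try:
                values.extend(float(tok) for tok in line.split())
            except ValueError as exc:
                raise FormatError(f"{path}: bad probability value ({exc})") from None
    flush()

    unknown = sorted(set(rows) - set(seqs.ids))
    if unknown:
        raise AlignmentError(f"{path}: unknown sequence ID(s) {unknown[:5]}")
    missing = [sid for sid in seqs.ids if sid not in rows]
    if missing:
        raise AlignmentError(f"{path}: missing sequence ID(s) {missing[:5]}")
    for sid in seqs.ids:
        if (rows[sid] < 0).any():
            raise FormatError(f"{path}: negative probability for sequence {sid!r}")
    prior = Prior(path.stem, tuple(rows[sid] for sid in seqs.ids), weight)
    prior.validate_against(seqs, k)
    return prior.floored(prob_floor)


def write_psp(prior: Prior, path: str | Path, seqs: SequenceSet, k: int) -> None:
    """Write a Prior in the PSP dialect (``#k=`` header, then FASTA-like rows)."""
    prior.validate_against(seqs, k)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#k={k}\n")
        for sid, row in zip(seqs.ids, prior.rows):
            fh.write(f">{sid}\n")
            fh.write(" ".join(format(v, ".12g") for v in row) + "\n")


def read_peaks(path: str | Path, seqs: SequenceSet, step: int = 25, df: float = 3.0) -> PeakSpec:
    """Read a two-column TSV (sequence ID, 0-based summit offset)."""
    summits: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected two columns")
        summits[parts[0]] = int(parts[1])
    spec = PeakSpec(summits, step=step, df=df)
    spec.validate_against(seqs)
    return spec


def uniform_prior(seqs: SequenceSet, k: int, weight: float = 1.0) -> Prior:
    """The uninformative prior: every admissible start equally likely."""
    seqs.require_min_length(k)
    rows = []
    for n in seqs.lengths:
        w = n - k + 1
        rows.append(np.full(w, 1.0 / w))
    return Prior("uniform", tuple(rows), weight)


def build_peak_psp(
    peaks: PeakSpec,
    seqs: SequenceSet,
    k: int,
    weight: float = 1.0,
) -> Prior:
    """Coverage-based prior from peak summits.

    The prior over window starts is proportional to a discretised Student t
    density (``df`` degrees of freedom) of the distance between the window
    centre ``j + floor(k/2)`` and the summit, rescaled to a step function
    with constant value inside each ``step``-bp band; each row is normalised
    to sum to 1, and the result is symmetric about the summit.
    """
    peaks.validate_against(seqs)
    seqs.require_min_length(k)
    rows = []
    for sid, n in zip(seqs.ids, seqs.lengths):
        summit = peaks.summits[sid]
        starts = np.arange(n - k + 1)
        dist = np.abs(starts + k // 2 - summit)
        step_idx = dist // peaks.step
        # density at the step's centre; all positions in a step share it
        centers = step_idx * peaks.step + peaks.step / 2.0
        raw = student_t.pdf(centers / peaks.step, df=peaks.df)
        rows.append(raw / raw.sum())
    return Prior("peak", tuple(rows), weight)


def normalize_weights(raw: Sequence[float]) -> np.ndarray:
    """Scale raw non-negative prior weights into a convex combination."""
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise ConfigError("no prior weights given")
    if (arr < 0).any():
        raise ConfigError(f"prior weights must be non-negative, got {arr}")
    total = arr.sum()
    if total <= 0:
        raise ConfigError("all prior weights are zero")
    return arr / total
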