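"""Synthetic planted-motif datasets and the recovery benchmark.

The generator emulates the ChIP-chip regime the discovery pipeline targets:
N (default 200) background sequences of n bp (default 500), each carrying
exactly one implanted occurrence of a width-k consensus mutated at a fixed
number of random positions (one occurrence per sequence, matching the
scoring model's one-annotation-per-sequence contract).  Alongside the
sequences it fabricates position-specific priors of controllable quality: a
fraction ``prior_concentration`` of each row's mass sits on the planted
start (optionally jittered by a Gaussian of ``prior_noise_sd`` bp) and the
remainder is spread uniformly.

What this does NOT emulate: real priors derive from conservation, duplex
energy or nucleosome maps and are broadly peaked and correlated across
positions; real backgrounds have composition bias and repeats.  Passing
recovery benchmarks here demonstrates the machinery, not field performance.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    Config,
    ConfigError,
    DNA_BASES,
    Motif,
    PSSM,
    SequenceSet,
    iupac_to_pssm,
    pssm_distance,
)
from .priors import Prior, uniform_prior, write_psp
from .search import discover
from .seeder import SeederParams, enumerate_seeds

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "generate_dataset",
    "recovery_benchmark",
    "BenchmarkArm",
    "write_dataset",
]

#: Default planted consensus: an E-box-like 8-mer (CACGTG core, as bound by
#: yeast Cbf1/Pho4), a realistic width-8 target.
DEFAULT_CONSENSUS = "TCACGTGA"


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic dataset."""

    consensus: str = DEFAULT_CONSENSUS
    n_sequences: int = 200
    length: int = 500
    mutations_per_occurrence: int = 2
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    prior_concentration: float = 0.5
    prior_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.consensus) - set(DNA_BASES):
            raise ConfigError("consensus must be a plain DNA word")
        k = len(self.consensus)
        if self.length < k:
            raise ConfigError(f"length {self.length} < motif width {k}")
        if not 0 <= self.mutations_per_occurrence <= k:
            raise ConfigError("mutations_per_occurrence must lie in [0, k]")
        if not 0.0 <= self.prior_concentration <= 1.0:
            raise ConfigError("prior_concentration must lie in [0, 1]")
        if self.prior_noise_sd < 0:
            raise ConfigError("prior_noise_sd must be >= 0")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg < 0).any() or abs(bg.sum() - 1.0) > 1e-9:
            raise ConfigError("background must be 4 probabilities summing to 1")
        if self.n_sequences < 1:
            raise ConfigError("need at least one sequence")

    @property
    def k(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class GroundTruth:
    """Where the motif really is: per-sequence start and implanted word."""

    consensus: str
    starts: tuple[int, ...]
    words: tuple[str, ...]

    @property
    def pssm(self) -> PSSM:
        return iupac_to_pssm(Motif(self.consensus), delta=0.0)

    def to_tsv(self, path: str | Path, seqs: SequenceSet) -> None:
        with open(path, "w") as fh:
            fh.write("sequence_id\tstart\tword\n")
            for sid, j, w in zip(seqs.ids, self.starts, self.words):
                fh.write(f"{sid}\t{j}\t{w}\n")


def _mutate(word: str, n_mut: int, rng: np.random.Generator) -> str:
    """Substitute exactly n_mut distinct positions, each to a different base."""
    chars = list(word)
    for pos in rng.choice(len(word), size=n_mut, replace=False):
        alternatives = [b for b in DNA_BASES if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def _informative_prior(
    name: str,
    starts: Sequence[int],
    lengths: Sequence[int],
    k: int,
    concentration: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> Prior:
    rows = []
    for start, n in zip(starts, lengths):
        w = n - k + 1
        center = start
        if noise_sd > 0:
            center = int(round(start + rng.normal(0.0, noise_sd)))
            center = min(max(center, 0), w - 1)
        row = np.full(w, (1.0 - concentration) / w)
        row[center] += concentration
        rows.append(row)
    return Prior(name, tuple(rows))


def generate_dataset(
    spec: SynthSpec,
    prior_specs: Sequence[tuple[float, float]] | None = None,
) -> tuple[SequenceSet, list[Prior], GroundTruth]:
    """Generate sequences, priors and ground truth, reproducibly from the seed.

    ``prior_specs`` is a list of (concentration, noise_sd) pairs, one per
    requested prior; by default one prior is built from the spec's own
    ``prior_concentration`` and ``prior_noise_sd``.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.k
    w = spec.length - k + 1
    ids, seqs, starts, words = [], [], [], []
    bg = np.asarray(spec.background, dtype=float)
    for i in range(spec.n_sequences):
        bases = rng.choice(4, size=spec.length, p=bg)
        seq = "".join(DNA_BASES[b] for b in bases)
        start = int(rng.integers(w))
        occurrence = _mutate(spec.consensus, spec.mutations_per_occurrence, rng)
        seq = seq[:start] + occurrence + seq[start + k :]
        ids.append(f"seq_{i:04d}")
        seqs.append(seq)
        starts.append(start)
        words.append(occurrence)
    sequence_set = SequenceSet(tuple(ids), tuple(seqs))
    truth = GroundTruth(spec.consensus, tuple(starts), tuple(words))

    if prior_specs is None:
        prior_specs = [(spec.prior_concentration, spec.prior_noise_sd)]
    priors = [
        _informative_prior(
            f"informative_{p}", starts, sequence_set.lengths, k, conc, sd, rng
        )
        for p, (conc, sd) in enumerate(prior_specs)
    ]
    return sequence_set, priors, truth


def write_dataset(
    spec: SynthSpec,
    out_dir: str | Path,
    prior_specs: Sequence[tuple[float, float]] | None = None,
) -> dict[str, Path]:
    """Generate and write FASTA + PSP file(s) + ground-truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs, priors, truth = generate_dataset(spec, prior_specs)
    paths = {"fasta": out_dir / "sequences.fasta", "truth": out_dir / "truth.tsv"}
    seqs.to_fasta(paths["fasta"])
    truth.to_tsv(paths["truth"], seqs)
    for p, prior in enumerate(priors):
        path = out_dir / f"prior_{p}.psp"
        write_psp(prior, path, seqs, spec.k)
        paths[f"psp_{p}"] = path
    return paths


@dataclass(frozen=True)
class BenchmarkArm:
    """One prior regime to benchmark.

    ``priors``: None for a prior-free run, "uniform" for the uninformative
    prior, or a sequence of indices into the benchmark's shared prior pool
    (so two arms, or one combined arm, can reference the very same built
    priors).
    """

    name: str
    priors: Sequence[int] | str | None = None


def recovery_benchmark(
    specs: Sequence[SynthSpec],
    arms: Sequence[BenchmarkArm],
    config: Config | None = None,
    replicates: int = 20,
    seed: int = 0,
    threshold: float = 0.25,
    prior_pool: Sequence[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Planted-motif recovery across spec x arm x replicate.

    For every run: generate a dataset, run discovery, and measure the scaled
    Euclidean distance between the reported motif's PSSM and the planted
    consensus PSSM; success means distance <= ``threshold``.  Within a
    replicate all arms share the same sequences, the same built priors
    (``prior_pool`` is a list of (concentration, noise_sd) pairs, default
    the spec's own values) and the same seed words (seeds depend only on
    the sequences), so arms differ purely in the prior information handed
    to the refinement.
    """
    config = config or Config()
    rows = []
    for spec_idx, spec in enumerate(specs):
        if spec.k != config.k:
            raise ConfigError(
                f"config k={config.k} does not match consensus width {spec.k}"
            )
        pool = list(prior_pool) if prior_pool is not None else [
            (spec.prior_concentration, spec.prior_noise_sd)
        ]
        for rep in range(replicates):
            rep_seed = (seed + 100_003 * spec_idx + 997 * rep) % (2**31 - 1)
            rep_spec = replace(spec, seed=rep_seed)
            seqs, built_priors, truth = generate_dataset(rep_spec, pool)
            params = SeederParams(
                k=config.k,
                e=config.e,
                quorum_count=max(1, int(np.ceil(config.quorum_frac * seqs.n_sequences))),
                z_min=config.z_min,
                z_max=config.z_max,
            )
            seed_words = [c.word for c in enumerate_seeds(seqs, params)[: config.z]]
            for arm in arms:
                if arm.priors is None:
                    run_priors: list[Prior] = []
                elif arm.priors == "uniform":
                    run_priors = [uniform_prior(seqs, config.k)]
                else:
                    run_priors = [built_priors[i] for i in arm.priors]
                t0 = time.perf_counter()
                result = discover(seqs, run_priors, config, seeds=seed_words)
                elapsed = time.perf_counter() - t0
                dist = pssm_distance(
                    iupac_to_pssm(result.motif, delta=0.0), truth.pssm
                )
                rows.append(
                    {
                        "spec": spec_idx,
                        "consensus": spec.consensus,
                        "mutations": spec.mutations_per_occurrence,
                        "arm": arm.name,
                        "replicate": rep,
                        "seed": rep_seed,
                        "motif": result.motif.symbols,
                        "distance": dist,
                        "success": dist <= threshold,
                        "bis": result.score,
                        "runtime_s": elapsed,
                        "n_seeds": len(seed_words),
                    }
                )
    return pd.DataFrame(rows)
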