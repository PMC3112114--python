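import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_sequence_set(rng, n_max=5, len_min=8, len_max=30):
    """Small random DNA sequence set for oracle tests."""
    from bismotif import SequenceSet

    n = int(rng.integers(1, n_max + 1))
    ids, seqs = [], []
    for i in range(n):
        length = int(rng.integers(len_min, len_max + 1))
        seqs.append("".join("ACGT"[b] for b in rng.integers(0, 4, size=length)))
        ids.append(f"s{i}")
    return SequenceSet(tuple(ids), tuple(seqs))


def random_prior(rng, seqs, k, name="p"):
    """Random strictly positive prior aligned to a sequence set."""
    from bismotif import Prior

    rows = []
    for n in seqs.lengths:
        row = rng.uniform(0.01, 1.0, size=n - k + 1)
        rows.append(row / row.sum())
    return Prior(name, tuple(rows), weight=float(rng.uniform(0.1, 2.0)))
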