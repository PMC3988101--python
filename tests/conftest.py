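import numpy as np
import pytest

from denovobench.transcriptome import TranscriptSet

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly n_subs distinct positions to a different base."""
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = BASES[(BASES.index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20140415)


@pytest.fixture
def toy_reference(rng):
    """Five random reference transcripts, 250-400 bp."""
    tx = TranscriptSet()
    for i in range(5):
        tx.add(f"ref{i}", random_seq(rng, int(rng.integers(250, 401))))
    return tx
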