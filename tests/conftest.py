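import numpy as np
import pytest

from lrquant import TranscriptSet, build_index, generate_transcriptome


@pytest.fixture(scope="session")
def toy_transcripts():
    """Three transcripts with a planted shared exon between t0 and t1."""
    return generate_transcriptome(
        3, length_range=(300, 400), shared_blocks=[(0, 1, 120)], seed=11
    )


@pytest.fixture(scope="session")
def toy_index(toy_transcripts):
    return build_index(toy_transcripts, k=31)


def random_fixture(rng, n_transcripts=None, k=31, shared=True):
    """A random transcriptome (optionally with shared blocks) and its index."""
    n = n_transcripts or int(rng.integers(2, 51))
    blocks = []
    if shared and n >= 2:
        for _ in range(int(rng.integers(0, 4))):
            i, j = rng.choice(n, size=2, replace=False)
            blocks.append((int(i), int(j), int(rng.integers(k + 5, 120))))
    ts = generate_transcriptome(
        n,
        length_range=(150, 400),
        shared_blocks=blocks,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return ts, build_index(ts, k=k)
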