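import numpy as np
import pytest

from tssbind.genome import GenomeLayout, Peak, PeakSet
from tssbind.simulate import (
    generate_compendium,
    generate_peaks,
    generate_world,
    paperlike_small,
)


@pytest.fixture
def toy_layout():
    """A 10 kb two-chromosome genome small enough for dense oracles."""
    return GenomeLayout((("chrA", 6000), ("chrB", 4000)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_peakset(layout, n, rng, min_len=20, max_len=200, scores=False):
    peaks = []
    for _ in range(n):
        chrom, L = layout.chromosomes[rng.integers(len(layout.chromosomes))]
        length = int(rng.integers(min_len, max_len))
        start = int(rng.integers(0, L - length))
        score = float(rng.random() * 10) if scores else None
        peaks.append(Peak(chrom, start, start + length, score))
    return PeakSet(peaks, layout=layout)


@pytest.fixture(scope="session")
def world():
    """The packaged default-scale synthetic world (fixed seed)."""
    return generate_world(paperlike_small(seed=1))


@pytest.fixture(scope="session")
def world_peaks(world):
    return generate_peaks(world)


@pytest.fixture(scope="session")
def compendium(world):
    """(query, tracks) for the packaged 50-track synthetic compendium."""
    return generate_compendium(world)
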