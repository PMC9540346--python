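import numpy as np
import pytest

from rretools.core import GeneModel, Peak
from rretools.synthetic import SyntheticConfig, make_genome, simulate_peaks_and_counts


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def default_genome(default_config):
    return make_genome(default_config)


@pytest.fixture(scope="session")
def default_sim(default_config, default_genome):
    return simulate_peaks_and_counts(default_config, default_genome)


def make_peak(chrom, center, width=200, peak_id=None, **kw):
    half = width // 2
    return Peak(
        chrom, center - half, center + width - half,
        peak_id or f"{chrom}:{center}", **kw,
    )


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=100_000, prefix="p"):
    peaks = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(50, 500))
        peaks.append(Peak(chrom, start, start + width, f"{prefix}{i}"))
    return peaks


@pytest.fixture
def toy_genes():
    return [
        GeneModel("g1", "chr1", 100_000, 101_000, "+"),
        GeneModel("g2", "chr1", 300_000, 305_000, "-"),
        GeneModel("g3", "chr2", 50_000, 52_000, "+"),
    ]
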