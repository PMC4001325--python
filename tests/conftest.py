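import numpy as np
import pytest

from polwave.genomic_io import GeneModel, GenomicInterval, SignalTrack


def make_gene(gene_id="g", chrom="chr1", start=0, end=60_000, strand="+",
              exons=None):
    if exons is None:
        exons = [(start, end)]
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand),
                     [GenomicInterval(chrom, a, b, strand) for a, b in exons])


def uniform_track(chrom="chr1", strand="+", start=0, end=60_000,
                  density=0.05, cell=50, rng=None):
    """Track with `density` reads/bp, Poisson-sampled per cell when rng given."""
    starts = np.arange(start, end, cell)
    mu = np.full(len(starts), density * cell)
    counts = rng.poisson(mu) if rng is not None else mu
    return SignalTrack.from_positions(chrom, strand, starts, counts, width=cell)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_gene():
    return make_gene()
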