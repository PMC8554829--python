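import numpy as np
import pytest

from popgenscan.variantio import VariantTable


def make_table(genotypes, pos=None, chrom="chr1", contig_len=None,
               samples=None, qual=100.0, qd=25.0, mq=50.0, mq0=0.0, dp=500.0,
               ref="A", alt="T"):
    """Small VariantTable from a sites x samples genotype list."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    pos = np.asarray(pos, dtype=np.int64)
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]

    def expand(v):
        a = np.asarray(v, dtype=float)
        return np.full(n_sites, float(v)) if a.ndim == 0 else a

    def bases(v):
        return (np.full(n_sites, v, dtype=object) if isinstance(v, str)
                else np.asarray(v, dtype=object))

    if contig_len is None:
        contig_len = int(pos.max()) + 10
    return VariantTable(
        chrom=np.full(n_sites, chrom, dtype=object), pos=pos,
        ref=bases(ref), alt=bases(alt),
        qual=expand(qual), qd=expand(qd), mq=expand(mq),
        mq0=expand(mq0), dp=expand(dp),
        samples=list(samples), gt=g, contigs={chrom: contig_len})


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def random_table(rng, n_sites=50, n_samples=10, missing_rate=0.05,
                 contig_len=None):
    """Random genotype table (sorted unique positions, some missing calls)."""
    pos = np.sort(rng.choice(np.arange(1, 100 * n_sites), n_sites,
                             replace=False))
    g = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    g[rng.random(g.shape) < missing_rate] = -1
    return make_table(g, pos=pos, contig_len=contig_len or int(pos.max()) + 50)
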