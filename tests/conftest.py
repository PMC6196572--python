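import numpy as np
import pytest

from methclust.io import GeneModel, IntervalTrack, MethylationSiteTable


def make_count_table(chrom, pos, meth, total, groups=None, samples=None):
    """Small count-mode table builder used across test modules."""
    meth = np.asarray(meth, dtype=float)
    total = np.asarray(total, dtype=float)
    n_samples = meth.shape[1]
    if samples is None:
        samples = [f"s{i+1}" for i in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = {s: ("A" if i < half else "B") for i, s in enumerate(samples)}
    return MethylationSiteTable(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        samples=samples,
        groups=groups,
        mode="count",
        meth=meth,
        total=total,
    )


def make_fraction_table(chrom, pos, percent, groups=None, samples=None):
    percent = np.asarray(percent, dtype=float)
    n_samples = percent.shape[1]
    if samples is None:
        samples = [f"s{i+1}" for i in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = {s: ("A" if i < half else "B") for i, s in enumerate(samples)}
    return MethylationSiteTable(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        samples=samples,
        groups=groups,
        mode="fraction",
        percent=percent,
    )


@pytest.fixture
def plus_gene():
    """A plus-strand gene [10000, 20000) with two exon blocks."""
    return GeneModel(
        gene_id="GPLUS", chrom="chr1", strand="+",
        tx_start=10_000, tx_end=20_000,
        exons=((10_000, 12_000), (18_000, 20_000)),
    )


@pytest.fixture
def minus_gene():
    """A minus-strand gene [5000, 9000); its promoter is [9000, 11000)."""
    return GeneModel(
        gene_id="GMINUS", chrom="chr2", strand="-",
        tx_start=5_000, tx_end=9_000,
        exons=((5_000, 9_000),),
    )


@pytest.fixture
def single_island():
    return IntervalTrack({"chr1": np.array([[1_000, 2_000]])})


def random_count_table(rng, n_sites=30, n_samples=4, missing_rate=0.0):
    chrom = np.where(rng.random(n_sites) < 0.5, "chr1", "chr2").astype(object)
    pos = rng.choice(np.arange(1, 10_000), size=n_sites, replace=False)
    total = rng.integers(1, 60, size=(n_sites, n_samples)).astype(float)
    meth = rng.binomial(total.astype(int), rng.random((n_sites, n_samples))).astype(float)
    if missing_rate:
        mask = rng.random((n_sites, n_samples)) < missing_rate
        meth[mask] = np.nan
        total[mask] = np.nan
    return make_count_table(chrom, pos, meth, total)
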