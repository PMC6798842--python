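import numpy as np
import pytest

from seedlong import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_gm():
    """Factory for small hand-built genotype matrices."""

    def _make(dosage, chrom=None, pos=None, ref=None, alt=None, accessions=None):
        dosage = np.asarray(dosage, dtype=float)
        n, m = dosage.shape
        if chrom is None:
            chrom = np.ones(m, dtype=int)
        if pos is None:
            pos = np.arange(1, m + 1) * 1000
        if accessions is None:
            accessions = [f"A{i}" for i in range(n)]
        return GenotypeMatrix(
            dosage=dosage,
            accessions=np.array(accessions, dtype=object),
            snp_ids=np.array([f"s{j}" for j in range(m)], dtype=object),
            chrom=np.asarray(chrom, dtype=int),
            pos=np.asarray(pos, dtype=int),
            ref=np.full(m, "A", dtype=object),
            alt=np.full(m, "G", dtype=object),
        )

    return _make
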