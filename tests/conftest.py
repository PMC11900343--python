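import numpy as np
import pytest

from popsweep.genotypes import MISSING, GenotypeMatrix, SampleInfo, SiteInfo


def make_gm(calls, positions=None, contig="chr1", qual=60.0, contig_length=None):
    """GenotypeMatrix from a plain dosage array (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    sites = [
        SiteInfo(contig=contig, position=int(p), ref_allele="A", alt_allele="G",
                 qual=qual)
        for p in positions
    ]
    samples = [SampleInfo(sample_id=f"S{i:03d}") for i in range(n)]
    lengths = {contig: contig_length} if contig_length else None
    return GenotypeMatrix(calls=calls, sites=sites, samples=samples,
                         contig_lengths=lengths)


def random_two_group_calls(rng, n1, n2, n_sites, missing_rate=0.1):
    """Two random dosage matrices sharing per-site frequencies, with missing."""
    p = rng.uniform(0.05, 0.95, size=n_sites)
    g1 = rng.binomial(2, p, size=(n1, n_sites)).astype(np.int8)
    g2 = rng.binomial(2, p, size=(n2, n_sites)).astype(np.int8)
    if missing_rate:
        g1[rng.random(g1.shape) < missing_rate] = MISSING
        g2[rng.random(g2.shape) < missing_rate] = MISSING
    return g1, g2


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
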