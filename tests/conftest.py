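import numpy as np
import pytest

from extremeprs import GenotypeTable, SnpWeight


def make_gt(rows, sample_ids=None, snp_ids=None):
    """Build a GenotypeTable from per-sample lists of 2-character calls.

    ``rows = [["AA", "AG"], ["GG", "00"]]`` is two samples at two SNPs;
    ``"00"`` is a missing call.
    """
    n, m = len(rows), len(rows[0])
    calls = np.array([[list(call) for call in row] for row in rows], dtype="<U1")
    return GenotypeTable(
        sample_ids=sample_ids or [f"S{i + 1}" for i in range(n)],
        snp_ids=snp_ids or [f"rs{j + 1}" for j in range(m)],
        calls=calls,
    )


def make_weight(snp_id="rs1", effect="A", other="G", beta=0.1,
                sets=("overall", "ER+", "ER-"), chrom="1", pos=1000):
    return SnpWeight(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=effect,
                     other_allele=other, beta=beta, sets=frozenset(sets))


def random_gt(rng, n=10, m=20, missing_rate=0.0, pairs=None):
    """Random biallelic table (with known allele pairs) for oracle tests."""
    if pairs is None:
        choices = [("A", "G"), ("C", "T"), ("G", "T"), ("A", "C")]
        pairs = [choices[int(rng.integers(len(choices)))] for _ in range(m)]
    freqs = rng.uniform(0.1, 0.9, size=m)
    dosage = rng.binomial(2, freqs, size=(n, m))
    calls = np.empty((n, m, 2), dtype="<U1")
    for j, (a, b) in enumerate(pairs):
        calls[:, j, 0] = np.where(dosage[:, j] >= 1, a, b)
        calls[:, j, 1] = np.where(dosage[:, j] == 2, a, b)
    if missing_rate > 0:
        miss = rng.random((n, m)) < missing_rate
        calls[miss] = "0"
    return GenotypeTable(
        sample_ids=[f"S{i + 1}" for i in range(n)],
        snp_ids=[f"rs{j + 1}" for j in range(m)],
        calls=calls,
    ), pairs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
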