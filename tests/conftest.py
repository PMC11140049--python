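import numpy as np
import pytest

from mrpipe import GwasRecord, HarmonizedSet, LdMatrix


def make_record(
    snp_id="rs1",
    chrom="1",
    pos=1000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pval=1e-9,
    n=10000.0,
) -> GwasRecord:
    return GwasRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def random_records(rng: np.random.Generator, n: int, chrom_count: int = 3):
    """Valid random records with unique ids, non-palindromic alleles."""
    pairs = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    recs = []
    for i in range(n):
        ea, oa = pairs[rng.integers(len(pairs))]
        recs.append(
            make_record(
                snp_id=f"rs{i + 1}",
                chrom=str(rng.integers(1, chrom_count + 1)),
                pos=int(rng.integers(1, 5_000_000)),
                ea=ea,
                oa=oa,
                eaf=float(rng.uniform(0.01, 0.99)),
                beta=float(rng.normal(0, 0.1)),
                se=float(rng.uniform(0.005, 0.05)),
                pval=float(rng.uniform(1e-12, 1.0)),
            )
        )
    return recs


def random_harmonized(rng: np.random.Generator, j: int) -> HarmonizedSet:
    return HarmonizedSet.from_arrays(
        beta_exp=rng.normal(0.1, 0.05, j),
        se_exp=rng.uniform(0.01, 0.03, j),
        beta_out=rng.normal(0.02, 0.03, j),
        se_out=rng.uniform(0.005, 0.02, j),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def identity_ld():
    def _make(records):
        ids = [r.snp_id for r in records]
        return LdMatrix(snp_ids=tuple(ids), r2=np.eye(len(ids)))

    return _make
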