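import numpy as np
import pytest

from mrkit.harmonize import HarmonizedSet
from mrkit.sumstats import GwasRecord, SummaryDataset


def make_record(
    variant_id="rs1",
    chrom="1",
    pos=1_000_000,
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pval=1e-8,
    eaf=0.3,
    n=100_000.0,
) -> GwasRecord:
    return GwasRecord(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pval=pval,
        eaf=eaf,
        n=n,
    )


def random_records(rng: np.random.Generator, n: int, prefix: str = "rs"):
    """Valid random GWAS records with distinct ids, suitable for round trips."""
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("A", "T"), ("C", "G")]
    records = []
    for i in range(n):
        ea, oa = pairs[rng.integers(len(pairs))]
        records.append(
            GwasRecord(
                variant_id=f"{prefix}{i + 1}",
                chrom=str(rng.integers(1, 23)),
                pos=int(rng.integers(1, 2**28)),
                effect_allele=ea,
                other_allele=oa,
                beta=float(rng.normal(0, 0.1)),
                se=float(rng.uniform(0.001, 0.05)),
                pval=float(rng.uniform(1e-30, 1.0)),
                eaf=None if rng.random() < 0.2 else float(rng.uniform(0, 1)),
                n=None if rng.random() < 0.2 else float(rng.integers(1e4, 1e6)),
            )
        )
    return records


def random_hset(rng: np.random.Generator, j: int) -> HarmonizedSet:
    return HarmonizedSet.from_arrays(
        beta_exposure=rng.uniform(0.02, 0.4, j) * rng.choice([-1, 1], j),
        se_exposure=rng.uniform(0.001, 0.02, j),
        beta_outcome=rng.normal(0, 0.05, j),
        se_outcome=rng.uniform(0.005, 0.05, j),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def dataset(rng):
    return SummaryDataset("trait", "exposure", random_records(rng, 20))
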