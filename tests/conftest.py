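import numpy as np
import pytest

from sweepstack import SampleInfo, SimParams, VariantTable, simulate_neutral


def make_variants(pos, chrom="1"):
    pos = np.asarray(pos, dtype=np.int64)
    n = pos.size
    return VariantTable(
        chrom=np.full(n, chrom, dtype=object),
        pos_bp=pos,
        snp_id=np.array([f"snp{chrom}_{p}" for p in pos], dtype=object),
        allele_a=np.full(n, "A", dtype=object),
        allele_b=np.full(n, "C", dtype=object),
        ancestral=np.full(n, "A", dtype=object),
    )


def make_samples(n, prefix="S"):
    return SampleInfo(np.array([f"{prefix}{i:03d}" for i in range(n)], dtype=object))


@pytest.fixture(scope="session")
def neutral_dataset():
    """A small neutral phased dataset reused across tests (deterministic)."""
    params = SimParams(
        n_diploids=30, seq_length_bp=1_000_000, mu=1e-7, r=2e-7,
        pop_size_N=150, seed=11,
    )
    haps, variants, truth = simulate_neutral(params)
    return haps, variants, truth, params
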