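import numpy as np
import pytest

from domescan.popgen import VariantTable


def make_table(genotypes, positions=None, contig="chr1", contig_length=None,
               samples=None, ref=None, alt=None):
    """Build a VariantTable from a dosage matrix (snps x samples)."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n_snps, n_samples = geno.shape
    if positions is None:
        positions = np.arange(1, n_snps + 1)
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    return VariantTable(
        contigs=np.array([contig] * n_snps, dtype=object),
        positions=np.asarray(positions),
        ref=np.array(ref if ref is not None else ["A"] * n_snps, dtype=object),
        alt=np.array(alt if alt is not None else ["G"] * n_snps, dtype=object),
        samples=list(samples),
        genotypes=geno,
        contig_lengths={contig: contig_length} if contig_length else {},
    )


@pytest.fixture(scope="session")
def sweep_dataset():
    """One default planted-sweep simulation shared across tests."""
    from domescan import simulate as sim

    cfg = sim.SweepSimConfig(seed=7)
    table, truth = sim.simulate_two_pop_variants(cfg)
    return cfg, table, truth
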