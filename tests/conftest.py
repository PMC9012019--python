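import numpy as np
import pytest

from popgenscan.vcfio import GenotypeMatrix


def make_gm(
    geno,
    pos=None,
    chrom=None,
    pops=None,
    samples=None,
    chrom_lengths=None,
):
    """Build a small genotype matrix from a (samples x sites) code array."""
    geno = np.asarray(geno, dtype=np.int8)
    n_samples, n_sites = geno.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    if chrom is None:
        chrom = ["1"] * n_sites
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if pops is None:
        pops = ["P"] * n_samples
    return GenotypeMatrix(
        samples=list(samples),
        populations=np.array(pops, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        geno=geno,
        chrom_lengths=chrom_lengths or {},
    )


@pytest.fixture(scope="session")
def sim_default():
    """One standard simulation with a known sweep, shared across tests."""
    from popgenscan.simdata import DemographyConfig, SweepSpec, simulate_truth

    cfg = DemographyConfig(seed=11)
    gm, sweeps = simulate_truth(cfg, [SweepSpec("1", 1_000_000, 100_000, 0.9)])
    return cfg, gm, sweeps
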