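import numpy as np
import pandas as pd
import pytest

from lsblscan.variants import GenotypeMatrix, SampleMap
from lsblscan.synthio import SimConfig, simulate_three_pop


def make_geno(dosage, positions=None, chrom="chr1", samples=None, chrom_len=None):
    """Build a small GenotypeMatrix from a (samples x sites) array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions), "ref": "A", "alt": "C"}
    )
    lengths = {chrom: chrom_len} if chrom_len else None
    return GenotypeMatrix(dosage, sites, list(samples), lengths)


def make_map(geno, populations):
    """Sample map assigning geno.samples to populations round-robin-free."""
    rows = [
        (s, populations[i], populations[i], "wild" if populations[i] == "wild" else "meat")
        for i, s in enumerate(geno.samples)
    ]
    return SampleMap(pd.DataFrame(rows, columns=["sample_id", "population", "breed", "type"]))


@pytest.fixture(scope="session")
def small_sim():
    """One modest three-population simulation shared across tests."""
    cfg = SimConfig(
        n_chrom=1, chrom_length_bp=5_000_000, n_sites=4000, n_per_pop=12, seed=11
    )
    return simulate_three_pop(cfg)
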