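import numpy as np
import pandas as pd
import pytest

from paddygwas import GenotypeMatrix, SyntheticConfig, simulate_genotypes


def make_matrix(dosage, positions=None, chrom="1", ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array (helper for toys)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if ids is None:
        ids = [f"A{i:03d}" for i in range(n)]
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(ids, markers, dosage)


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Compact panel used across module tests: 3 chromosomes, causal loci on
    chromosomes 1-3, enough markers for LD and association structure."""
    return SyntheticConfig(
        n_chromosomes=3,
        n_markers_per_chrom=1200,
        chrom_length_bp=10_000_000,
        major_locus=(1, 4_866_454),
        modifier_loci=((2, 7_780_702), (3, 958_898)),
        switch_rate=5e-6,
        seed=20_240_322,
    )


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    return simulate_genotypes(small_cfg)
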