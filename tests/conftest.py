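import numpy as np
import pytest

import rohtrack as rt


@pytest.fixture(scope="session")
def small_map() -> rt.SnpMap:
    """Two chromosomes, 300 loci each over 12 Mb (~40 kb spacing)."""
    return rt.generate_snp_map(2, 300, 12_000_000, seed=42)


@pytest.fixture(scope="session")
def hotspot_cohort(small_map):
    """40 samples with one mid-frequency hotspot per chromosome plus
    private segments; returns (genotypes, truth, hotspots)."""
    spots = [
        rt.Hotspot(1, 3_000_000, 6_000_000, 0.5),
        rt.Hotspot(2, 5_000_000, 8_000_000, 0.3),
    ]
    g, truth = rt.generate_cohort(
        small_map,
        n_samples=40,
        het_rate=0.3,
        error_rate=0.01,
        nocall_rate=0.01,
        hotspots=spots,
        private_roh_rate=0.2,
        private_roh_mean_len_bp=2_000_000,
        seed=7,
    )
    return g, truth, spots


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120209)
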