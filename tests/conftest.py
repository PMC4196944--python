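import numpy as np
import pytest

from poolsweep import PoolSiteCounts, SimulationConfig, simulate_sync


def make_site(chrom="chr1", pos=100, ref="A", pools=((10, 2, 0, 0, 0, 0),)):
    """A PoolSiteCounts with counts in sync order (A, T, C, G, N, del)."""
    return PoolSiteCounts(
        chrom=chrom, pos=pos, ref_allele=ref,
        counts=np.array(pools, dtype=np.int64),
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study: 2-Mb genome, one planted sweep."""
    cfg = SimulationConfig(
        seed=11,
        genome=(("chr1", 2_000_000),),
        sweeps=(("chr1", 800_000, 860_000),),
    )
    truth, sites = simulate_sync(cfg)
    return cfg, truth, sites


@pytest.fixture(scope="session")
def null_study():
    """No drift, no sweeps: domestic pools identical to the wild source."""
    cfg = SimulationConfig(
        seed=7,
        genome=(("chr1", 1_200_000),),
        drift_c=0.0,
        sweeps=(),
    )
    truth, sites = simulate_sync(cfg)
    return cfg, truth, sites
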