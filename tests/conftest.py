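import numpy as np
import pytest

from sweepscan.synthetic_data import SimConfig, SweepSpec, simulate

SMALL_CONFIG = SimConfig(
    seed=7,
    scaffolds=(("chr1", 400_000), ("chr2", 150_000)),
    snp_per_mb=1500,
    sweep=SweepSpec(scaffold="chr1", start=150_000, end=250_000),
)


@pytest.fixture(scope="session")
def small_sim():
    """A cheap sweep dataset: 400 kb + 150 kb scaffolds, ~825 SNPs."""
    return simulate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_null_sim():
    return simulate(SMALL_CONFIG.no_sweep())


@pytest.fixture(scope="session")
def default_sim():
    """The full default study conditions (2 Mb + 200 kb, sweep at 0.9-1.1 Mb)."""
    return simulate(SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
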