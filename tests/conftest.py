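import numpy as np
import pytest

from hapblocks import DiplotypeCaller, simulate_locus
from hapblocks.simulate import LocusConfig


@pytest.fixture(scope="session")
def small_cfg():
    return LocusConfig(n_individuals=300, seed=11)


@pytest.fixture(scope="session")
def small_locus(small_cfg):
    """A 300-individual three-clade planted-block locus."""
    return simulate_locus(small_cfg, seed=11)


@pytest.fixture(scope="session")
def block_region(small_cfg):
    start, end = small_cfg.block_span_bp
    return f"{small_cfg.chrom}:{start}-{end}"


@pytest.fixture(scope="session")
def small_calls(small_locus, block_region):
    gm, _ = small_locus
    caller = DiplotypeCaller(n_alleles=3, region=block_region, random_state=0)
    caller.fit(gm)
    return caller


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
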