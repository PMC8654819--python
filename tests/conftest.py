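import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from circlenom import (ReferenceGenome, SgRNASpec, SimParams, make_genome,
                       plant_sites, simulate_reads)

SPACER = "GAGTCCGAGCAGAAGAAGAA"


@pytest.fixture(scope="session")
def sgrna() -> SgRNASpec:
    return SgRNASpec(SPACER)


@pytest.fixture(scope="session")
def planted():
    """A small planted genome: on-target plus 1/2/3-mismatch off-targets."""
    genome = make_genome(11, 1, 30_000)
    sg = SgRNASpec(SPACER)
    genome, sites = plant_sites(genome, sg, [0, 1, 2, 3], seed=11)
    return genome, sites, sg


@pytest.fixture(scope="session")
def small_sim(planted):
    """One simulated sample library over the planted genome."""
    genome, sites, sg = planted
    params = SimParams(seed=4, depth_per_site=80, background_pairs=120)
    return genome, sites, sg, params, simulate_reads(genome, sites, params)
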