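import numpy as np
import pytest

from nucspec.synthetic_data import (FacsPopulation, PlantedSite, SelexSimSpec,
                                    SimConfig)
from nucspec.targets import SELEX_FLANK3, SELEX_FLANK5


@pytest.fixture
def rng():
    return np.random.default_rng(20160107)


@pytest.fixture
def small_site():
    return PlantedSite(name="site1", chrom="chr1", position=5000,
                       sequence="ACGTTGCAGGTCATCGATCGGATATCCGGTA",  # 31 bp
                       kind="off", intensity=5.0)


@pytest.fixture
def capture_config(small_site):
    return SimConfig(seed=7, genome_length=100_000, n_chromosomes=1,
                     planted_sites=(small_site,), background_rate=0.0,
                     capture_offset_scale=50.0)


@pytest.fixture
def uniform_selex_config():
    L = 22
    uniform = tuple(tuple(0.25 for _ in range(L)) for _ in range(4))
    return SimConfig(seed=3, selex=SelexSimSpec(
        flank5=SELEX_FLANK5, flank3=SELEX_FLANK3, matrix=uniform))


@pytest.fixture
def facs_config():
    return SimConfig(seed=11, facs=(
        FacsPopulation(weight=0.9, log_mean_gfp=4.0, log_sd_gfp=0.5,
                       log_mean_mcherry=4.0, log_sd_mcherry=0.5),
        FacsPopulation(weight=0.1, log_mean_gfp=7.0, log_sd_gfp=0.4,
                       log_mean_mcherry=4.5, log_sd_mcherry=0.5),
    ))
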