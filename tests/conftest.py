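import numpy as np
import pytest

from nanochrome.optics import ParticleModel, load_gold_constants
from nanochrome.pipeline import RunConfig
from nanochrome.simulate import (
    BandResponseTable,
    ImagingConfig,
    PopulationConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def gold():
    return load_gold_constants()


@pytest.fixture(scope="session")
def bare_80nm():
    return ParticleModel(core_diameter=80.0, shell_thickness=0.0)


@pytest.fixture(scope="session")
def band_table():
    """Band-response lookup for the default population (built once)."""
    return BandResponseTable(PopulationConfig())


@pytest.fixture(scope="session")
def nc_dataset(band_table):
    """A small negative-control dataset with default imaging noise."""
    return generate_dataset(0.0, n_spots=1200, seed=314, table=band_table)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Negative-control frames with all noise sources disabled."""
    pop = PopulationConfig()
    img = ImagingConfig(shot_noise=False, read_noise_sd=0.0)
    table = BandResponseTable(pop)
    return generate_dataset(0.0, n_spots=600, pop=pop, img=img, seed=99, table=table)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(n_spots=2000)
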