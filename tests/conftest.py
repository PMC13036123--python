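import numpy as np
import pandas as pd
import pytest

import indicot as ic


@pytest.fixture(scope="session")
def default_config():
    return ic.GeneratorConfig()


@pytest.fixture(scope="session")
def default_table(default_config):
    """Default seeded factorial experiment with the 14 index columns."""
    return ic.add_vegetation_indices(ic.generate_experiment(default_config))


@pytest.fixture(scope="session")
def noiseless_table():
    return ic.generate_experiment(ic.GeneratorConfig().noiseless())


@pytest.fixture(scope="session")
def default_indi(default_table):
    return ic.build_indi(default_table)


@pytest.fixture()
def toy_bands():
    return {"blue": 0.05, "green": 0.1, "red": 0.08, "red_edge": 0.25, "nir": 0.45}


@pytest.fixture()
def tiny_raster():
    """Deterministic 10x10 five-band raster with a nodata border."""
    rng = np.random.default_rng(42)
    bands = rng.uniform(0.05, 0.6, size=(5, 10, 10))
    mask = np.ones((10, 10), dtype=bool)
    mask[0, :] = False
    mask[:, -1] = False
    bands[:, ~mask] = np.nan
    return ic.RasterGrid(bands=bands, band_names=ic.BAND_NAMES, pixel_size=0.5)
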