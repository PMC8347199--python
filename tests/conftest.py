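import numpy as np
import pytest

from hypospec import GeneratorConfig, default_band_library, synth_dataset


@pytest.fixture(scope="session")
def library():
    return default_band_library()


@pytest.fixture(scope="session")
def default_grid():
    """The generator's channel axis (3180 channels over 200-3400 cm^-1)."""
    return GeneratorConfig().make_grid()


@pytest.fixture(scope="session")
def small_config():
    """Two maps per class of 10 spectra on a coarse grid: fast structural checks."""
    return GeneratorConfig(
        n_maps_per_class=2, spectra_per_map=10, grid=(200.0, 3400.0, 800), seed=7
    )


@pytest.fixture(scope="session")
def small_dataset(small_config, library):
    return synth_dataset(small_config, library)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
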