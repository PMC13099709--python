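import numpy as np
import pytest

from cutaway import (
    classify_hydro,
    generate_site,
    kampinneva_like_config,
    load_background,
    load_constants,
    load_registry,
    site_suitability,
)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def constants():
    return load_constants()


@pytest.fixture(scope="session")
def background():
    return load_background()


@pytest.fixture(scope="session")
def preset_site():
    return generate_site(kampinneva_like_config(rng_seed=0))


@pytest.fixture(scope="session")
def preset_hydro(preset_site):
    return classify_hydro(preset_site)


@pytest.fixture(scope="session")
def preset_suitability(preset_site, preset_hydro):
    return site_suitability(preset_site, preset_hydro)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
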