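import numpy as np
import pytest

from reefniche.predictor_stack import derive_predictors
from reefniche.synthetic_reefscape import (
    ReefScapeConfig,
    default_species_specs,
    generate_reefscape,
    generate_sites,
)
from reefniche.wave_energy import WaveParams, compute_fetch, wave_energy_raster


@pytest.fixture(scope="session")
def small_config() -> ReefScapeConfig:
    return ReefScapeConfig(
        grid_nrows=40, grid_ncols=60, n_days=45, n_sites=300,
        n_subregions=10, seed=7,
    )


@pytest.fixture(scope="session")
def small_scape(small_config):
    return generate_reefscape(small_config)


@pytest.fixture(scope="session")
def small_layers(small_scape):
    fetch = compute_fetch(small_scape.land_mask, edge_policy="open")
    wave = wave_energy_raster(
        small_scape.land_mask, small_scape.env.wind_speed,
        small_scape.env.wind_direction, fetch, WaveParams(),
    )
    return derive_predictors(small_scape, wave)


@pytest.fixture(scope="session")
def small_sites(small_config, small_scape, small_layers):
    return generate_sites(
        small_config, small_scape.reef_mask, small_layers,
        default_species_specs(),
        rng=np.random.default_rng(11),
    )
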