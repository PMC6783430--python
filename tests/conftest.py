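"""Shared fixtures: synthetic worlds and trained ensembles at two scales.

The "small" world (2 deg) keeps unit tests fast; the "default" world runs at
the package's standard study conditions (0.5 deg) for the acceptance-level
checks that are defined at those conditions.
"""

import numpy as np
import pytest

from ocean_ch4.disequilibrium import (bin_climatology, delta_ch4,
                                      mixed_layer_filter)
from ocean_ch4.mapping import build_training_table, generate_ensemble
from ocean_ch4.synthetic import (SyntheticWorldConfig, make_world,
                                 mld_climatology)


def build_climatology(world):
    cfg = world.config
    kept = mixed_layer_filter(world.observations, mld_climatology)
    records = delta_ch4(kept, world.atmosphere)
    return bin_climatology(records, cfg.resolution, cfg.lat_extent,
                           cfg.lon_extent, depth_field=world.fields["depth_m"])


@pytest.fixture(scope="session")
def small_config():
    return SyntheticWorldConfig(resolution=2.0, seed=0)


@pytest.fixture(scope="session")
def small_world(small_config):
    return make_world(small_config)


@pytest.fixture(scope="session")
def small_climatology(small_world):
    return build_climatology(small_world)


@pytest.fixture(scope="session")
def small_table(small_world, small_climatology):
    return build_training_table(small_climatology, small_world.fields)


@pytest.fixture(scope="session")
def small_ensemble(small_table, small_world):
    return generate_ensemble(small_table, small_world.fields, n_members=3,
                             seed=42)


@pytest.fixture(scope="session")
def default_world():
    return make_world(SyntheticWorldConfig(seed=0))


@pytest.fixture(scope="session")
def default_ensemble(default_world):
    clim = build_climatology(default_world)
    table = build_training_table(clim, default_world.fields)
    return generate_ensemble(table, default_world.fields, n_members=10,
                             seed=11)


@pytest.fixture(scope="session")
def spectrum_curve(small_world):
    """Spectrum-integrated transfer-efficiency curve on a depth grid."""
    from ocean_ch4.ebullition import efficiency_curve

    depths = np.concatenate([np.arange(1.0, 30.0, 2.0),
                             np.arange(30.0, 101.0, 5.0),
                             np.arange(110.0, 201.0, 10.0)])
    return efficiency_curve(small_world.bubble_spectrum, depths)
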