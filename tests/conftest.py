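import numpy as np
import pytest

from gridscape import CategoricalRaster, PopulationRaster, RaceGridSet
from gridscape.grid_io import GROUPS_7
from gridscape import synthetic as syn


def cat(values, cell_size_m=30.0, **kw):
    """Shorthand: build a CategoricalRaster from a nested list."""
    return CategoricalRaster(values=np.asarray(values, dtype=np.int32),
                             cell_size_m=cell_size_m, **kw)


def pop(values, cell_size_m=30.0, **kw):
    return PopulationRaster(values=np.asarray(values, dtype=float),
                            cell_size_m=cell_size_m, **kw)


def grid_set_from_stack(stack7, cell_size_m=30.0):
    """RaceGridSet from a (7, r, c) people/cell array in canonical group order."""
    stack7 = np.asarray(stack7, dtype=float)
    rasters = {g: pop(stack7[i], cell_size_m) for i, g in enumerate(GROUPS_7)}
    return RaceGridSet(groups=GROUPS_7, rasters=rasters,
                       total=pop(stack7.sum(axis=0), cell_size_m))


def random_map(rng, shape=(8, 8), n_classes=4, p_background=0.2):
    """Random small categorical raster with codes 1..n_classes and 0 background."""
    vals = rng.integers(1, n_classes + 1, size=shape)
    vals[rng.random(shape) < p_background] = 0
    return cat(vals)


@pytest.fixture(scope="session")
def scenario():
    """Gaussian-cluster scenario: (truth RaceGridSet, ZoneMap, config)."""
    cfg = syn.ScenarioConfig(shape=(60, 60), n_zones=12, seed=7)
    truth, zone_map = syn.make_population_scenario(cfg)
    return truth, zone_map, cfg


@pytest.fixture(scope="session")
def proportional_scenario():
    cfg = syn.ScenarioConfig(shape=(80, 80), n_zones=20, seed=3)
    truth, zone_map, weights = syn.make_proportional_scenario(cfg)
    return truth, zone_map, weights, cfg
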