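"""Synthetic scenarios with known ground truth for every pipeline stage.

Real inputs to the pipeline are census block counts plus a land-cover
raster; neither is redistributable at desk scale, so this module generates
aligned stand-ins with controlled properties:

* a 3-class land-cover raster (urban / vegetation / uninhabited) as a
  thresholded smoothed Gaussian random field with requested class
  fractions;
* contiguous zones (emulating census blocks) grown by multi-source BFS
  from random seed cells, so every zone is 4-connected by construction;
* per-group population surfaces as Gaussian clusters centred on urban
  cells (full strength on urban, 0.15x on vegetation, zero on uninhabited),
  aggregated exactly to the zone table — so the zone counts are, by
  construction, the zone sums of the true grid.

:func:`make_proportional_scenario` builds the special case in which the
true grid is exactly proportional to land-cover class weights within every
zone; there, weight estimation and disaggregation must recover the truth
exactly, which pins down the correctness of the dasymetric stage.

One integer seed drives all draws (a single ``numpy.random.default_rng``;
draw order is fixed), so every fixture is bit-reproducible.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dasymetric import ZoneMap
from .errors import ConfigError
from .grid_io import GROUPS_7, CategoricalRaster, PopulationRaster, RaceGridSet

__all__ = [
    "ScenarioConfig",
    "GroupProfile",
    "LANDCOVER_LEGEND",
    "URBAN",
    "VEGETATION",
    "UNINHABITED",
    "make_landcover",
    "make_zones",
    "make_population_scenario",
    "make_proportional_scenario",
]

URBAN, VEGETATION, UNINHABITED = 1, 2, 3
LANDCOVER_LEGEND = {URBAN: "urban", VEGETATION: "vegetation", UNINHABITED: "uninhabited"}

#: Default peak densities (people/km^2) at cluster centres, roughly
#: urban-census-like magnitudes per group.
_DEFAULT_PEAKS = {
    "NHW": 5000.0,
    "NHB": 3000.0,
    "NHAS": 1500.0,
    "NHAM": 300.0,
    "NHPI": 100.0,
    "NHO": 200.0,
    "H": 2500.0,
}


@dataclass(frozen=True)
class GroupProfile:
    """Spatial profile of one group: cluster count, peak density, decay radius."""

    name: str
    n_clusters: int = 2
    peak_density_km2: float = 3000.0
    radius_cells: float = 10.0


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic study area.

    ``fractions`` are the (urban, vegetation, uninhabited) land-cover
    shares and must sum to 1.
    """

    shape: tuple[int, int] = (200, 200)
    cell_size_m: float = 30.0
    n_zones: int = 60
    fractions: tuple[float, float, float] = (0.30, 0.50, 0.20)
    groups: tuple[GroupProfile, ...] = ()
    vegetation_factor: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 2:
            raise ConfigError(f"degenerate grid shape {self.shape}")
        if abs(sum(self.fractions) - 1.0) > 1e-9 or min(self.fractions) < 0:
            raise ConfigError("land-cover fractions must be non-negative and sum to 1")
        if self.n_zones < 1:
            raise ConfigError("need at least one zone")
        if self.n_zones > self.shape[0] * self.shape[1]:
            raise ConfigError("more zones than cells")
        if not self.groups:
            self.groups = tuple(
                GroupProfile(g, n_clusters=2, peak_density_km2=_DEFAULT_PEAKS[g],
                             radius_cells=max(6.0, min(self.shape) / 15.0))
                for g in GROUPS_7
            )


def make_landcover(cfg: ScenarioConfig) -> CategoricalRaster:
    """3-class land-cover raster with class fractions within ~2% of requested.

    A Gaussian random field is smoothed and split at the empirical
    quantiles of the requested fractions (urban = lowest quantile band).
    """
    rng = np.random.default_rng(cfg.seed)
    field_ = gaussian_filter(rng.standard_normal(cfg.shape), sigma=max(2.0, min(cfg.shape) / 40.0))
    urban_f, veg_f, _ = cfg.fractions
    q1 = np.quantile(field_, urban_f)
    q2 = np.quantile(field_, urban_f + veg_f)
    values = np.full(cfg.shape, UNINHABITED, dtype=np.int32)
    values[field_ <= q2] = VEGETATION
    values[field_ <= q1] = URBAN
    if urban_f == 0:
        values[values == URBAN] = VEGETATION
    if veg_f == 0:
        values[values == VEGETATION] = UNINHABITED if urban_f == 0 else URBAN
    return CategoricalRaster(
        values=values, legend=dict(LANDCOVER_LEGEND), cell_size_m=cfg.cell_size_m
    )


def make_zones(cfg: ScenarioConfig) -> CategoricalRaster:
    """Partition the grid into ``n_zones`` contiguous, non-empty zones.

    Multi-source breadth-first growth from random distinct seed cells;
    every zone is 4-connected by construction.  Zone ids run 1..n_zones.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    nr, nc = cfg.shape
    n = cfg.n_zones
    seeds = rng.choice(nr * nc, size=n, replace=False)
    zone = np.zeros(nr * nc, dtype=np.int32)
    queue: deque[int] = deque()
    for i, s in enumerate(seeds, start=1):
        zone[s] = i
        queue.append(int(s))
    while queue:
        s = queue.popleft()
        r, c = divmod(s, nc)
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < nr and 0 <= cc < nc:
                t = rr * nc + cc
                if zone[t] == 0:
                    zone[t] = zone[s]
                    queue.append(t)
    legend = {i: f"zone_{i}" for i in range(1, n + 1)}
    return CategoricalRaster(
        values=zone.reshape(cfg.shape), legend=legend, cell_size_m=cfg.cell_size_m
    )


def _as_population(values: np.ndarray, cfg: ScenarioConfig) -> PopulationRaster:
    return PopulationRaster(values=values, cell_size_m=cfg.cell_size_m)


def _aggregate_to_table(stack: dict[str, np.ndarray], zones: CategoricalRaster) -> pd.DataFrame:
    zidx = zones.values.ravel()
    ids = np.unique(zidx)
    data = {}
    for g, arr in stack.items():
        data[g] = np.bincount(zidx, weights=arr.ravel(), minlength=ids.max() + 1)[ids]
    tbl = pd.DataFrame(data, index=pd.Index(ids, name="zone_id"))
    tbl["total"] = tbl.sum(axis=1)
    return tbl


def make_population_scenario(cfg: ScenarioConfig) -> tuple[RaceGridSet, ZoneMap]:
    """Gaussian-cluster truth grids plus the zone table aggregated from them.

    Returns the true :class:`RaceGridSet` and a :class:`ZoneMap` whose
    table sums equal the true grid's zone sums exactly (by construction).
    """
    landcover = make_landcover(cfg)
    zones = make_zones(cfg)
    rng = np.random.default_rng(cfg.seed + 2)
    nr, nc = cfg.shape
    rows, cols = np.mgrid[0:nr, 0:nc]
    habit = np.where(
        landcover.values == URBAN, 1.0,
        np.where(landcover.values == VEGETATION, cfg.vegetation_factor, 0.0),
    )
    centre_pool = np.flatnonzero((landcover.values == URBAN).ravel())
    if centre_pool.size == 0:
        centre_pool = np.flatnonzero((landcover.values == VEGETATION).ravel())
    cell_area_km2 = cfg.cell_size_m**2 / 1e6
    stack: dict[str, np.ndarray] = {}
    for prof in cfg.groups:
        surf = np.zeros(cfg.shape)
        if centre_pool.size:
            centres = rng.choice(centre_pool, size=prof.n_clusters, replace=True)
            for s in centres:
                cr, cc = divmod(int(s), nc)
                d2 = (rows - cr) ** 2 + (cols - cc) ** 2
                surf += prof.peak_density_km2 * np.exp(-d2 / (2.0 * prof.radius_cells**2))
        stack[prof.name] = surf * habit * cell_area_km2  # people/cell
    table = _aggregate_to_table(stack, zones)
    total_vals = np.sum([stack[g] for g in stack], axis=0)
    grids = RaceGridSet(
        groups=tuple(stack),
        rasters={g: _as_population(v, cfg) for g, v in stack.items()},
        total=_as_population(total_vals, cfg),
    )
    zone_map = ZoneMap(zone_raster=zones, zone_table=table, groups=tuple(stack))
    return grids, zone_map


def make_proportional_scenario(
    cfg: ScenarioConfig, class_weights: dict[int, float] | None = None
) -> tuple[RaceGridSet, ZoneMap, dict[int, float]]:
    """Truth exactly proportional to land-cover class weights within zones.

    Every cell's total count equals the class weight of its land-cover
    class (default urban 5, vegetation 1, uninhabited 0 people/cell), and
    group shares are constant within each zone (drawn from a Dirichlet).
    Disaggregation from the aggregated zone table must reproduce this
    truth exactly; returns (truth, zone map, weights used).
    """
    if class_weights is None:
        class_weights = {URBAN: 5.0, VEGETATION: 1.0, UNINHABITED: 0.0}
    landcover = make_landcover(cfg)
    zones = make_zones(cfg)
    rng = np.random.default_rng(cfg.seed + 3)
    total = np.zeros(cfg.shape)
    for code, w in class_weights.items():
        total[landcover.values == code] = w
    zvals = zones.values
    ids = np.unique(zvals)
    group_names = tuple(p.name for p in cfg.groups)
    shares = rng.dirichlet(np.ones(len(group_names)), size=len(ids))
    share_grid = {g: np.zeros(cfg.shape) for g in group_names}
    for zi, z in enumerate(ids):
        mask = zvals == z
        for gi, g in enumerate(group_names):
            share_grid[g][mask] = shares[zi, gi]
    stack = {g: total * share_grid[g] for g in group_names}
    table = _aggregate_to_table(stack, zones)
    grids = RaceGridSet(
        groups=group_names,
        rasters={g: _as_population(v, cfg) for g, v in stack.items()},
        total=_as_population(total, cfg),
    )
    zone_map = ZoneMap(zone_raster=zones, zone_table=table, groups=group_names)
    return grids, zone_map, class_weights
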