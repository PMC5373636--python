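"""Dasymetric disaggregation of zone-aggregated population counts.

Census counts are published per irregular statistical zone (blocks in the
source data); a categorical land-cover raster of higher resolution serves as
ancillary information.  The model here is intentionally simple:

1. :func:`estimate_class_weights` fits one relative density weight per
   land-cover class (people per cell) by non-negative least squares of the
   zone totals on the zone class composition.  The declared uninhabited
   class is forced to weight zero.
2. :func:`disaggregate_total` spreads each zone's total count over its cells
   proportionally to the class weights and renormalizes within the zone, so
   every zone's grid sum reproduces its census count exactly (pycnophylactic
   property).
3. :func:`disaggregate_subpopulations` reuses the per-cell weights of the
   total population for each race/ethnicity sub-population — i.e. group
   proportions are constant within a zone; the grids place sub-populations
   away from uninhabited land but do not model sub-zone mixing gradients.

A populated zone whose cells all carry zero class weight cannot be spread
proportionally; the documented fallback spreads its count uniformly over
the zone and emits a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import FitError, ValidationError
from .grid_io import (
    GROUPS_7,
    CategoricalRaster,
    PopulationRaster,
    RaceGridSet,
    assert_aligned,
)

__all__ = [
    "ZoneMap",
    "WeightTable",
    "estimate_class_weights",
    "disaggregate_total",
    "disaggregate_subpopulations",
    "read_zone_table",
]


@dataclass
class ZoneMap:
    """A zone-id raster plus the per-zone population table.

    ``zone_table`` is indexed by zone id with one column per group plus a
    ``total`` column.  Every id in the table must occur in the raster and
    vice versa, and group counts must sum to the total in every zone.
    """

    zone_raster: CategoricalRaster
    zone_table: pd.DataFrame
    groups: tuple[str, ...] = GROUPS_7

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        tbl = self.zone_table
        missing_cols = [c for c in (*self.groups, "total") if c not in tbl.columns]
        if missing_cols:
            raise ValidationError(f"zone table missing columns {missing_cols}")
        if (tbl[list(self.groups) + ["total"]].to_numpy() < 0).any():
            raise ValidationError("zone table contains negative counts")
        gsum = tbl[list(self.groups)].sum(axis=1).to_numpy()
        tot = tbl["total"].to_numpy(dtype=float)
        if not np.allclose(gsum, tot, rtol=1e-6, atol=1e-6):
            bad = tbl.index[~np.isclose(gsum, tot, rtol=1e-6, atol=1e-6)].tolist()
            raise ValidationError(f"group counts do not sum to total in zones {bad[:5]}")
        raster_ids = set(
            int(z) for z in np.unique(self.zone_raster.values) if z != self.zone_raster.nodata
        )
        table_ids = set(int(z) for z in tbl.index)
        if raster_ids != table_ids:
            raise ValidationError(
                f"zone ids mismatch: only-in-raster {sorted(raster_ids - table_ids)[:5]}, "
                f"only-in-table {sorted(table_ids - raster_ids)[:5]}"
            )

    @property
    def zone_ids(self) -> np.ndarray:
        return self.zone_table.index.to_numpy()


@dataclass
class WeightTable:
    """Per-land-cover-class relative density weights (people per cell).

    The uninhabited class is pinned to zero; weights are non-negative and at
    least one must be positive for disaggregation to be meaningful.
    """

    weights: dict[int, float]
    uninhabited_code: int

    def __post_init__(self) -> None:
        self.weights = {int(k): float(v) for k, v in self.weights.items()}
        if any(v < 0 for v in self.weights.values()):
            raise ValidationError("class weights must be non-negative")
        self.weights[self.uninhabited_code] = 0.0

    def as_grid(self, ancillary: CategoricalRaster) -> np.ndarray:
        """Map per-class weights onto the ancillary raster (nodata -> 0)."""
        out = np.zeros(ancillary.shape, dtype=np.float64)
        for code, w in self.weights.items():
            out[ancillary.values == code] = w
        out[ancillary.values == ancillary.nodata] = 0.0
        return out


def read_zone_table(path, groups: tuple[str, ...] = GROUPS_7) -> pd.DataFrame:
    """Read a zone-count CSV with header ``zone_id,<groups...>,total``."""
    tbl = pd.read_csv(path)
    if "zone_id" not in tbl.columns:
        raise ValidationError("zone table CSV must have a zone_id column")
    return tbl.set_index("zone_id")


def _zone_index(zones: ZoneMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat arrays: valid-cell flat indices, their 0-based zone index, zone ids."""
    zvals = zones.zone_raster.values.ravel()
    valid = zvals != zones.zone_raster.nodata
    ids = zones.zone_ids
    order = pd.Index(ids)
    zidx = order.get_indexer(zvals[valid])
    return np.flatnonzero(valid), zidx, ids


def estimate_class_weights(zones: ZoneMap, ancillary: CategoricalRaster) -> WeightTable:
    """Fit per-class density weights by non-negative least squares.

    The design matrix counts cells of each inhabited ancillary class per
    zone; the response is the zone total count.  The class declared
    uninhabited in the ancillary legend (see ``uninhabited_code`` below) is
    excluded from the fit and pinned to zero.

    The uninhabited code is taken from the legend entry named
    ``"uninhabited"`` (case-insensitive); if absent, no class is pinned.

    Raises
    ------
    FitError
        If no inhabited-class cells exist anywhere (all-zero design).
    """
    assert_aligned([zones.zone_raster, ancillary])
    uninhabited = _uninhabited_code(ancillary)
    valid_flat, zidx, ids = _zone_index(zones)
    anc = ancillary.values.ravel()[valid_flat]

    classes = sorted(
        int(c) for c in np.unique(anc)
        if c != ancillary.nodata and c != uninhabited
    )
    n_zones = len(ids)
    X = np.zeros((n_zones, len(classes)), dtype=np.float64)
    for j, c in enumerate(classes):
        X[:, j] = np.bincount(zidx[anc == c], minlength=n_zones)
    y = zones.zone_table["total"].to_numpy(dtype=np.float64)

    if X.size == 0 or not X.any():
        raise FitError("no inhabited ancillary classes present; cannot fit weights")
    if not y.any():
        warnings.warn("all zone totals are zero; all class weights set to 0", stacklevel=2)
        w = np.zeros(len(classes))
    else:
        w, _ = nnls(X, y)
    table = {c: float(wi) for c, wi in zip(classes, w)}
    if uninhabited is not None:
        table[uninhabited] = 0.0
    return WeightTable(weights=table, uninhabited_code=uninhabited if uninhabited is not None else -9999)


def _uninhabited_code(ancillary: CategoricalRaster) -> int | None:
    for code, name in ancillary.legend.items():
        if str(name).strip().lower() == "uninhabited":
            return int(code)
    return None


def disaggregate_total(
    zones: ZoneMap, ancillary: CategoricalRaster, weights: WeightTable
) -> tuple[PopulationRaster, np.ndarray]:
    """Spread each zone's total count over its cells by class weight.

    Within zone *z*, cell *c* receives ``T_z * w(c)`` where
    ``w(c) = weight(class(c)) / sum over the zone``; per-zone grid sums equal
    the census totals exactly (a residual of at most ~1e-9 relative, from
    floating-point summation, is folded into the zone's heaviest cell).

    Returns the total-population raster and the per-cell weight grid
    ``w(c)`` (zeros outside the study area; per-zone sums equal 1 for every
    populated zone) for reuse on sub-populations.
    """
    assert_aligned([zones.zone_raster, ancillary])
    valid_flat, zidx, ids = _zone_index(zones)
    n_zones = len(ids)
    cell_w = weights.as_grid(ancillary).ravel()[valid_flat]

    zone_wsum = np.bincount(zidx, weights=cell_w, minlength=n_zones)
    zone_cells = np.bincount(zidx, minlength=n_zones)
    totals = zones.zone_table["total"].to_numpy(dtype=np.float64)

    # uniform-spread fallback for populated zones with no weighted cells
    fallback = (zone_wsum <= 0) & (totals > 0)
    if fallback.any():
        warnings.warn(
            f"{int(fallback.sum())} populated zone(s) have zero total class weight; "
            "spreading their counts uniformly",
            stacklevel=2,
        )
        in_fb = fallback[zidx]
        cell_w = cell_w.copy()
        cell_w[in_fb] = 1.0
        zone_wsum = np.bincount(zidx, weights=cell_w, minlength=n_zones)

    denom = np.where(zone_wsum > 0, zone_wsum, 1.0)
    wgrid_flat = cell_w / denom[zidx]
    counts_flat = totals[zidx] * wgrid_flat

    # fold the per-zone floating-point residual into the heaviest cell
    got = np.bincount(zidx, weights=counts_flat, minlength=n_zones)
    resid = totals - got
    if np.any(resid != 0):
        df = pd.DataFrame({"z": zidx, "w": wgrid_flat})
        top = df.groupby("z")["w"].idxmax()
        for z in np.flatnonzero(resid):
            if zone_cells[z] and totals[z] > 0:
                counts_flat[top.loc[z]] += resid[z]

    shape = zones.zone_raster.shape
    values = np.zeros(shape[0] * shape[1], dtype=np.float64)
    values[valid_flat] = counts_flat
    wgrid = np.zeros_like(values)
    wgrid[valid_flat] = wgrid_flat

    raster = PopulationRaster(
        values=values.reshape(shape),
        cell_size_m=zones.zone_raster.cell_size_m,
        origin=zones.zone_raster.origin,
        crs_tag=zones.zone_raster.crs_tag,
        nodata=-1.0,
    )
    # mark cells outside the study area
    raster.values[zones.zone_raster.values == zones.zone_raster.nodata] = raster.nodata
    return raster, wgrid.reshape(shape)


def disaggregate_subpopulations(zones: ZoneMap, wgrid: np.ndarray) -> RaceGridSet:
    """Distribute each group's zone counts with the total-population weights.

    Group *g* in zone *z* is spread as ``G_z * w(c)``; consequently the
    per-cell sum over groups equals the disaggregated total and per-zone
    per-group grid sums recover the zone table.
    """
    zr = zones.zone_raster
    if wgrid.shape != zr.shape:
        raise ValidationError("weight grid shape does not match the zone raster")
    valid_flat, zidx, ids = _zone_index(zones)
    w = np.asarray(wgrid, dtype=np.float64).ravel()[valid_flat]
    shape = zr.shape
    nodata_mask = (zr.values == zr.nodata)

    def spread(zone_counts: np.ndarray) -> PopulationRaster:
        flat = np.zeros(shape[0] * shape[1], dtype=np.float64)
        flat[valid_flat] = zone_counts[zidx] * w
        vals = flat.reshape(shape)
        vals[nodata_mask] = -1.0
        return PopulationRaster(
            values=vals, cell_size_m=zr.cell_size_m, origin=zr.origin,
            crs_tag=zr.crs_tag, nodata=-1.0,
        )

    rasters = {
        g: spread(zones.zone_table[g].to_numpy(dtype=np.float64)) for g in zones.groups
    }
    total = spread(zones.zone_table["total"].to_numpy(dtype=np.float64))
    return RaceGridSet(groups=zones.groups, rasters=rasters, total=total)
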