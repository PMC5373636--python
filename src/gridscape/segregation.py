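"""Classical unit-based segregation indices, with grid-to-unit aggregation.

One advantage of gridded population data is that counts for *any* areal
partition (tracts, ZIP codes, school districts) can be aggregated directly
from the cells.  This module aggregates a race grid set to a unit table and
computes the three classical indices used for cross-checking grid-based
analyses:

* dissimilarity ``D`` (two-group evenness, group vs. rest by default),
* isolation ``I`` (exposure of a group to itself),
* multigroup information-theory index ``H`` (Theil), over all groups.

All three are invariant to a uniform rescaling of counts, equal 0 under
exact evenness (D, H), and equal 1 under complete separation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid_io import CategoricalRaster, RaceGridSet, assert_aligned

__all__ = ["aggregate_grid_to_units", "dissimilarity", "isolation", "multigroup_H"]

log = logging.getLogger(__name__)


def aggregate_grid_to_units(grids: RaceGridSet, units: CategoricalRaster) -> pd.DataFrame:
    """Sum per-group cell values within each unit of a unit-id raster.

    Returns a table indexed by unit id with one column per group plus
    ``total``; grand totals are preserved exactly (cells outside the unit
    raster's coverage, i.e. nodata, are dropped).
    """
    assert_aligned([grids.total, units])
    uvals = units.values.ravel()
    valid = uvals != units.nodata
    if not valid.any():
        raise ValidationError("unit raster has no valid cells overlapping the grid")
    ids, uidx = np.unique(uvals[valid], return_inverse=True)
    data = {}
    for g in grids.groups:
        vals = np.where(grids.rasters[g].mask_valid(), grids.rasters[g].values, 0.0).ravel()
        data[g] = np.bincount(uidx, weights=vals[valid], minlength=len(ids))
    tot = np.where(grids.total.mask_valid(), grids.total.values, 0.0).ravel()
    data["total"] = np.bincount(uidx, weights=tot[valid], minlength=len(ids))
    return pd.DataFrame(data, index=pd.Index(ids, name="unit_id"))


def _drop_empty_units(table: pd.DataFrame) -> pd.DataFrame:
    empty = table["total"] <= 0
    if empty.any():
        log.info("dropping %d unit(s) with zero population", int(empty.sum()))
    return table.loc[~empty]


def dissimilarity(table: pd.DataFrame, group: str, reference: str | None = None) -> float:
    """Index of dissimilarity ``D = 1/2 sum_j |x_j/X - y_j/Y|``.

    ``y`` is everyone outside ``group`` (all other groups combined) unless a
    ``reference`` group is named.  D is 0 under identical unit proportions
    and 1 under complete separation.
    """
    if group not in table.columns:
        raise ValidationError(f"group {group!r} not in unit table")
    t = _drop_empty_units(table)
    x = t[group].to_numpy(dtype=float)
    if reference is None:
        y = t["total"].to_numpy(dtype=float) - x
    else:
        if reference not in t.columns:
            raise ValidationError(f"reference group {reference!r} not in unit table")
        y = t[reference].to_numpy(dtype=float)
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ValidationError("dissimilarity undefined: a group total is zero")
    return float(0.5 * np.abs(x / X - y / Y).sum())


def isolation(table: pd.DataFrame, group: str) -> float:
    """Isolation index ``I = sum_j (x_j/X)(x_j/t_j)``.

    The population-weighted average, over members of the group, of the
    group's share in their own unit.
    """
    if group not in table.columns:
        raise ValidationError(f"group {group!r} not in unit table")
    t = _drop_empty_units(table)
    x = t[group].to_numpy(dtype=float)
    tot = t["total"].to_numpy(dtype=float)
    X = x.sum()
    if X <= 0:
        raise ValidationError("isolation undefined: group total is zero")
    return float(((x / X) * (x / tot)).sum())


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def multigroup_H(table: pd.DataFrame, groups: list[str] | None = None) -> float:
    """Multigroup information-theory (Theil) index.

    ``H = sum_j t_j (E_tot - E_j) / (E_tot * T)`` with natural-log group
    entropies; 0 when every unit mirrors the overall composition, 1 when
    every unit is single-group.
    """
    if groups is None:
        groups = [c for c in table.columns if c != "total"]
    t = _drop_empty_units(table)
    if len(t) < 2:
        raise ValidationError("multigroup H needs at least 2 populated units")
    counts = t[groups].to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    overall = counts.sum(axis=0)
    if (overall > 0).sum() < 2:
        raise ValidationError("multigroup H undefined for a single-group population")
    e_tot = _entropy(overall)
    T = totals.sum()
    e_j = np.array([_entropy(row) for row in counts])
    return float((totals * (e_tot - e_j)).sum() / (e_tot * T))
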