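"""Patch delineation and landscape metrics for categorical diversity rasters.

A diversity map has the same data format as a land-cover map, so the
machinery of landscape ecology applies unchanged: a *patch* is a maximal
connected component of equal-code cells (8-neighbour connectivity by
default, 4 available), and pattern is quantified by class-level metrics
(one community at a time) and landscape-level metrics (the whole mosaic).

Implemented metrics (FRAGSTATS nomenclature):

=========  =====================================================  ========
name       meaning                                                units
=========  =====================================================  ========
PLAND      percentage of landscape area per class                 %
NP         number of patches                                      count
LPI        largest patch index (largest patch / landscape area)   %
TE         total edge between unlike classes                      m
AREA_MN    mean patch area                                        ha
AREA_AM    area-weighted mean patch area                          ha
GYRATE_MN  mean radius of gyration (centroid-to-cell distance)    m
GYRATE_AM  area-weighted radius of gyration                       m
ENN_MN     mean Euclidean nearest-neighbour distance              m
ENN_AM     area-weighted nearest-neighbour distance               m
AI         aggregation index (like-adjacency / maximum possible)  0..100
MESH       effective mesh size (sum of patch area^2 / A)          ha
CONTAG     contagion (adjacency-entropy clumpiness)               0..100
IJI        interspersion & juxtaposition index                    0..100
SHDI       Shannon diversity of class areas                       >= 0
SHEI       Shannon evenness (SHDI / ln m)                         0..1
PR         patch richness (number of classes)                     count
TECI       total edge contrast index (needs a contrast matrix)    0..100
=========  =====================================================  ========

The landscape area ``A`` is the *inhabited* area: background codes
(uninhabited, code 0, plus nodata) are excluded from ``A`` and, by
default, edges between a class and background are excluded from all edge
tallies (TE, CONTAG, IJI, TECI).

Undefined values are reported as NaN, never as 0: ENN for a class with a
single patch, AI for a single-cell class, IJI with fewer than 3 classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ValidationError
from .grid_io import CategoricalRaster
from . import diversity as _dv

__all__ = [
    "PatchSet",
    "label_patches",
    "adjacency_table",
    "class_metrics",
    "landscape_metrics",
    "MetricsReport",
    "compute_metrics",
    "max_like_adjacencies",
    "validate_contrast",
    "default_diversity_contrast",
]

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)

CLASS_METRIC_COLUMNS = [
    "PLAND", "NP", "LPI", "TE", "AREA_MN", "AREA_AM", "GYRATE_MN", "GYRATE_AM",
    "ENN_MN", "ENN_AM", "AI", "MESH",
]
LANDSCAPE_METRIC_NAMES = [
    "NP", "LPI", "TE", "AI", "MESH", "CONTAG", "IJI", "TECI", "SHDI", "SHEI", "PR",
]


@dataclass
class PatchSet:
    """Patch-id raster plus one record per patch.

    ``patch_ids`` holds 0 on background; ids run 1..NP.  ``patches`` is
    indexed by patch id with columns ``class_code``, ``cells``, ``area_ha``,
    ``perimeter_m``, ``centroid_row``, ``centroid_col``.
    """

    patch_ids: np.ndarray
    patches: pd.DataFrame
    cell_size_m: float
    connectivity: int
    raster: CategoricalRaster

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def classes(self) -> np.ndarray:
        return np.sort(self.patches["class_code"].unique())

    @property
    def total_area_ha(self) -> float:
        return float(self.patches["area_ha"].sum())


def _background_mask(raster: CategoricalRaster, background: Iterable[int]) -> np.ndarray:
    bg = set(int(b) for b in background) | {int(raster.nodata)}
    return np.isin(raster.values, sorted(bg))


def label_patches(
    raster: CategoricalRaster,
    connectivity: int = 8,
    background: Iterable[int] = (0,),
) -> PatchSet:
    """Delineate maximal connected components of equal-code cells.

    Background codes (default: 0 = uninhabited) and nodata are excluded;
    an empty foreground yields an empty PatchSet.
    """
    if connectivity not in (4, 8):
        raise ValidationError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = _STRUCT8 if connectivity == 8 else _STRUCT4
    bg = _background_mask(raster, background)
    values = raster.values
    patch_ids = np.zeros(values.shape, dtype=np.int32)
    records: list[dict] = []
    next_id = 1
    cell_ha = raster.cell_size_m**2 / 1e4
    for code in sorted(int(c) for c in np.unique(values[~bg])):
        mask = (values == code) & ~bg
        lab, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        lab_flat = lab.ravel()
        on = lab_flat > 0
        idx = lab_flat[on]
        rows, cols = np.divmod(np.flatnonzero(on), values.shape[1])
        cells = np.bincount(idx, minlength=n + 1)[1:]
        crow = np.bincount(idx, weights=rows, minlength=n + 1)[1:] / cells
        ccol = np.bincount(idx, weights=cols, minlength=n + 1)[1:] / cells
        # internal rook adjacencies per patch, for the perimeter
        same_h = (lab[:, :-1] == lab[:, 1:]) & (lab[:, :-1] > 0)
        same_v = (lab[:-1, :] == lab[1:, :]) & (lab[:-1, :] > 0)
        internal = (
            np.bincount(lab[:, :-1][same_h].ravel(), minlength=n + 1)[1:]
            + np.bincount(lab[:-1, :][same_v].ravel(), minlength=n + 1)[1:]
        )
        perim = (4 * cells - 2 * internal) * raster.cell_size_m
        patch_ids[lab > 0] = lab[lab > 0] + next_id - 1
        for k in range(n):
            records.append(
                {
                    "patch_id": next_id + k,
                    "class_code": code,
                    "cells": int(cells[k]),
                    "area_ha": cells[k] * cell_ha,
                    "perimeter_m": float(perim[k]),
                    "centroid_row": float(crow[k]),
                    "centroid_col": float(ccol[k]),
                }
            )
        next_id += n
    patches = pd.DataFrame(
        records,
        columns=[
            "patch_id", "class_code", "cells", "area_ha", "perimeter_m",
            "centroid_row", "centroid_col",
        ],
    ).set_index("patch_id")
    return PatchSet(
        patch_ids=patch_ids,
        patches=patches,
        cell_size_m=raster.cell_size_m,
        connectivity=connectivity,
        raster=raster,
    )


def adjacency_table(
    raster: CategoricalRaster, background: Iterable[int] = (0,)
) -> pd.DataFrame:
    """Symmetric class-by-class counts of shared cell edges (single count).

    Edges where either side is background or nodata are excluded; rook
    (4-neighbour) adjacency, as edges are shared cell sides.
    """
    bg = _background_mask(raster, background)
    v = np.where(bg, np.iinfo(np.int32).min, raster.values)
    classes = sorted(int(c) for c in np.unique(raster.values[~bg]))
    n = len(classes)
    lut = {c: i for i, c in enumerate(classes)}
    S = np.zeros((n, n), dtype=np.int64)
    for a, b in (
        (v[:, :-1].ravel(), v[:, 1:].ravel()),
        (v[:-1, :].ravel(), v[1:, :].ravel()),
    ):
        ok = (a != np.iinfo(np.int32).min) & (b != np.iinfo(np.int32).min)
        ia = np.array([lut[c] for c in a[ok]], dtype=np.int64) if ok.any() else np.array([], dtype=np.int64)
        ib = np.array([lut[c] for c in b[ok]], dtype=np.int64) if ok.any() else np.array([], dtype=np.int64)
        lo, hi = np.minimum(ia, ib), np.maximum(ia, ib)
        np.add.at(S, (lo, hi), 1)
    S = S + np.triu(S, 1).T  # mirror upper triangle -> symmetric, diagonal single-count
    return pd.DataFrame(S, index=classes, columns=classes)


def max_like_adjacencies(cells: int) -> int:
    """Maximum possible single-count like adjacencies of a class of given size.

    From the largest-square construction: with ``n = floor(sqrt(a))`` and
    ``m = a - n^2``: ``2n(n-1)`` if ``m = 0``; ``2n(n-1) + 2m - 1`` if
    ``m <= n``; ``2n(n-1) + 2m - 2`` if ``m > n``.
    """
    a = int(cells)
    n = int(np.floor(np.sqrt(a)))
    m = a - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def _gyrate_per_patch(ps: PatchSet) -> pd.Series:
    """Mean centroid-to-cell-centre distance per patch, metres."""
    pid = ps.patch_ids.ravel()
    on = pid > 0
    if not on.any():
        return pd.Series(dtype=float)
    idx = pid[on]
    rows, cols = np.divmod(np.flatnonzero(on), ps.patch_ids.shape[1])
    n = int(idx.max())
    crow = ps.patches["centroid_row"].reindex(range(1, n + 1)).to_numpy()
    ccol = ps.patches["centroid_col"].reindex(range(1, n + 1)).to_numpy()
    d = np.hypot(rows - crow[idx - 1], cols - ccol[idx - 1])
    sums = np.bincount(idx, weights=d, minlength=n + 1)[1:]
    cells = ps.patches["cells"].reindex(range(1, n + 1)).to_numpy()
    return pd.Series(sums / cells * ps.cell_size_m, index=ps.patches.index)


def _enn_per_patch(ps: PatchSet) -> pd.Series:
    """Euclidean nearest-neighbour distance per patch (same class), metres.

    Cell-centre to cell-centre between the two nearest member cells; NaN
    for the only patch of its class.
    """
    out = pd.Series(np.nan, index=ps.patches.index, dtype=float)
    pid = ps.patch_ids
    flat = pid.ravel()
    on = flat > 0
    coords_all = np.column_stack(np.divmod(np.flatnonzero(on), pid.shape[1])).astype(float)
    ids_all = flat[on]
    for code, grp in ps.patches.groupby("class_code"):
        if len(grp) < 2:
            continue
        member = np.isin(ids_all, grp.index.to_numpy())
        coords = coords_all[member]
        ids = ids_all[member]
        for p in grp.index:
            own = ids == p
            tree = cKDTree(coords[~own])
            dmin = tree.query(coords[own])[0].min()
            out.loc[p] = dmin * ps.cell_size_m
    return out


def class_metrics(ps: PatchSet, adjacency: pd.DataFrame | None = None) -> pd.DataFrame:
    """Class-level metrics table, one row per class code.

    ENN is NaN for single-patch classes; AI is NaN for single-cell classes.
    """
    if ps.n_patches == 0:
        return pd.DataFrame(columns=CLASS_METRIC_COLUMNS)
    if adjacency is None:
        adjacency = adjacency_table(ps.raster)
    A = ps.total_area_ha
    gyrate = _gyrate_per_patch(ps)
    enn = _enn_per_patch(ps)
    rows = {}
    for code, grp in ps.patches.groupby("class_code"):
        a = grp["area_ha"].to_numpy()
        a_i = a.sum()
        cells_i = int(grp["cells"].sum())
        g = gyrate.loc[grp.index].to_numpy()
        e = enn.loc[grp.index].to_numpy()
        gii = int(adjacency.loc[code, code]) if code in adjacency.index else 0
        max_gii = max_like_adjacencies(cells_i)
        unlike = (
            float(adjacency.loc[code].sum() - adjacency.loc[code, code])
            if code in adjacency.index
            else 0.0
        )
        rows[code] = {
            "PLAND": 100.0 * a_i / A,
            "NP": len(grp),
            "LPI": 100.0 * a.max() / A,
            "TE": unlike * ps.cell_size_m,
            "AREA_MN": a.mean(),
            "AREA_AM": float((a**2).sum() / a_i),
            "GYRATE_MN": float(g.mean()),
            "GYRATE_AM": float((g * a).sum() / a_i),
            "ENN_MN": float(np.mean(e)) if not np.isnan(e).any() else np.nan,
            "ENN_AM": float((e * a).sum() / a_i) if not np.isnan(e).any() else np.nan,
            "AI": 100.0 * gii / max_gii if max_gii > 0 else np.nan,
            "MESH": float((a**2).sum() / A),
        }
    return pd.DataFrame.from_dict(rows, orient="index")[CLASS_METRIC_COLUMNS].sort_index()


def validate_contrast(contrast: pd.DataFrame, classes: Sequence[int]) -> pd.DataFrame:
    """Check a contrast (dissimilarity) matrix: symmetric, zero diagonal, [0, 1]."""
    missing = [c for c in classes if c not in contrast.index or c not in contrast.columns]
    if missing:
        raise ValidationError(f"contrast matrix lacks classes {missing}")
    sub = contrast.loc[list(classes), list(classes)].astype(float)
    arr = sub.to_numpy()
    if not np.allclose(arr, arr.T):
        raise ValidationError("contrast matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValidationError("contrast matrix must have a zero diagonal")
    if arr.min() < 0 or arr.max() > 1:
        raise ValidationError("contrast weights must lie in [0, 1]")
    return sub


def default_diversity_contrast(codes: Sequence[int]) -> pd.DataFrame:
    """Documented default dissimilarity matrix between community labels.

    Between categories with *different* dominant groups the contrast starts
    at 1 for two low-diversity communities and grades down with diversity:
    ``1 - 0.25 * (div_i + div_k)`` with diversity indexed low=0, medium=1,
    high=2 (the high-diversity category has no dominant group and always
    counts as "different").  Between categories sharing a dominant group
    the contrast is ``0.15 * |div_i - div_k|``.  A density-class gap adds
    ``0.05`` per step.  Values are clipped to [0, 1]; the diagonal is 0.
    """
    codes = sorted(int(c) for c in codes)
    div_idx = {"low": 0, "medium": 1, "high": 2}
    comp = {c: _dv.label_components(c) for c in codes}
    n = len(codes)
    M = np.zeros((n, n))
    for i, ci in enumerate(codes):
        for j, ck in enumerate(codes):
            if ci == ck:
                continue
            li, lk = comp[ci], comp[ck]
            if li.code == 0 or lk.code == 0:
                M[i, j] = 1.0
                continue
            di, dk = div_idx[li.diversity], div_idx[lk.diversity]
            if li.dominant != lk.dominant:
                d = 1.0 - 0.25 * (di + dk)
            else:
                d = 0.15 * abs(di - dk)
            dens_i = ("low", "medium", "high").index(li.density) if li.density else 0
            dens_k = ("low", "medium", "high").index(lk.density) if lk.density else 0
            d += 0.05 * abs(dens_i - dens_k)
            M[i, j] = min(max(d, 0.0), 1.0)
    return pd.DataFrame(M, index=codes, columns=codes)


def landscape_metrics(
    ps: PatchSet,
    adjacency: pd.DataFrame | None = None,
    contrast: pd.DataFrame | None = None,
) -> pd.Series:
    """Landscape-level metrics of the whole mosaic.

    ``contrast`` (a class-by-class dissimilarity matrix) is required only
    for TECI, which is NaN when absent.  IJI is NaN with fewer than 3
    classes; CONTAG is 100 for a single-class landscape.
    """
    if ps.n_patches == 0:
        return pd.Series(np.nan, index=LANDSCAPE_METRIC_NAMES)
    if adjacency is None:
        adjacency = adjacency_table(ps.raster)
    cm = class_metrics(ps, adjacency)
    classes = cm.index.to_numpy()
    m = len(classes)
    A = ps.total_area_ha
    a_i = ps.patches.groupby("class_code")["area_ha"].sum().loc[classes].to_numpy()
    P = a_i / A
    S = adjacency.loc[classes, classes].to_numpy(dtype=float)

    # CONTAG from double-count adjacencies
    if m == 1:
        contag = 100.0
    else:
        D = S + np.diag(np.diag(S))
        rowsum = D.sum(axis=1)
        acc = 0.0
        for i in range(m):
            if rowsum[i] <= 0:
                continue
            for k in range(m):
                if D[i, k] > 0:
                    q = P[i] * D[i, k] / rowsum[i]
                    acc += q * np.log(q)
        contag = 100.0 * (1.0 + acc / (2.0 * np.log(m)))

    # IJI from the unlike-edge distribution
    iu = np.triu_indices(m, 1)
    e_ik = S[iu]
    E = e_ik.sum()
    if m < 3 or E <= 0:
        iji = np.nan
    else:
        q = e_ik[e_ik > 0] / E
        iji = 100.0 * (-(q * np.log(q)).sum()) / np.log(m * (m - 1) / 2.0)

    # TECI
    if contrast is None or E <= 0:
        teci = np.nan
    else:
        Cm = validate_contrast(contrast, classes).to_numpy()
        teci = 100.0 * float((e_ik * Cm[iu]).sum() / E)

    shdi = float(-(P * np.log(P)).sum())
    shei = shdi / np.log(m) if m > 1 else 0.0
    ai_cls = cm["AI"].to_numpy()
    defined = ~np.isnan(ai_cls)
    ai = float((P[defined] * ai_cls[defined]).sum()) if defined.any() else np.nan

    return pd.Series(
        {
            "NP": float(ps.n_patches),
            "LPI": 100.0 * ps.patches["area_ha"].max() / A,
            "TE": float(E * ps.cell_size_m),
            "AI": ai,
            "MESH": float((ps.patches["area_ha"] ** 2).sum() / A),
            "CONTAG": contag,
            "IJI": iji,
            "TECI": teci,
            "SHDI": shdi,
            "SHEI": float(shei),
            "PR": float(m),
        }
    )


@dataclass
class MetricsReport:
    """Class-level table plus landscape-level series for one map."""

    class_table: pd.DataFrame
    landscape: pd.Series
    connectivity: int


def compute_metrics(
    raster: CategoricalRaster,
    connectivity: int = 8,
    background: Iterable[int] = (0,),
    contrast: pd.DataFrame | None = None,
) -> MetricsReport:
    """Delineate patches and compute all class- and landscape-level metrics."""
    ps = label_patches(raster, connectivity=connectivity, background=background)
    adj = adjacency_table(raster, background=background)
    return MetricsReport(
        class_table=class_metrics(ps, adj),
        landscape=landscape_metrics(ps, adj, contrast=contrast),
        connectivity=connectivity,
    )
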