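"""Raster data model and GeoTIFF input/output.

Two in-memory raster types are shared by every stage of the pipeline:

* :class:`PopulationRaster` — a 2-D grid of people per cell (non-negative
  reals), with cell size in metres, an upper-left origin, and a nodata
  sentinel for cells outside the study area.
* :class:`CategoricalRaster` — a 2-D grid of integer codes with a legend
  mapping each code to a name (land-cover classes, zone ids, diversity
  labels, areal units).

Grids are stored as single-band GeoTIFFs.  Population grids are written as
float64, categorical grids as int32.  Georeferencing is carried by the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA and
GeoAsciiParams for the CRS string) so the files open directly in GDAL-based
GIS software.  Legends are persisted in a JSON side-car next to the TIFF
(``<path>.legend.json``) because baked-in value tables are not part of the
baseline TIFF model.

Conventions: arrays are row-major with (row 0, col 0) at the upper-left
corner; a cell is identified by its centre in all distance computations;
people/cell is the canonical storage unit, with people/km^2 derived on
demand.  ``nodata`` means "outside the study area" and is distinct from a
zero count ("inhabitable, nobody lives here").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import AlignmentError, GridFormatError, ValidationError

__all__ = [
    "PopulationRaster",
    "CategoricalRaster",
    "RaceGridSet",
    "GROUPS_7",
    "read_categorical",
    "write_categorical",
    "read_population",
    "write_population",
    "counts_to_density",
    "density_to_counts",
    "assert_aligned",
]

#: Census race/ethnicity groups, in the fixed canonical order used everywhere.
GROUPS_7 = ("NHW", "NHB", "NHAS", "NHAM", "NHPI", "NHO", "H")

# GeoTIFF tag ids
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113


@dataclass
class PopulationRaster:
    """People-per-cell grid with georeferencing metadata.

    Parameters
    ----------
    values
        2-D float array, people per cell.  Non-nodata values must be >= 0.
    cell_size_m
        Edge length of a (square) cell in metres; must be positive.
    origin
        (x, y) map coordinates of the upper-left corner of the grid.
    crs_tag
        Opaque CRS identifier carried through I/O (e.g. ``"EPSG:5070"``).
    nodata
        Sentinel marking cells outside the study area.
    """

    values: np.ndarray
    cell_size_m: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = ""
    nodata: float = -1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("population raster must be 2-D")
        if not self.cell_size_m > 0:
            raise ValidationError(f"cell_size_m must be positive, got {self.cell_size_m}")
        valid = self.values[self.values != self.nodata]
        if valid.size and np.nanmin(valid) < 0:
            raise ValidationError("population raster contains negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask_valid(self) -> np.ndarray:
        """Boolean mask of cells inside the study area."""
        return self.values != self.nodata

    def copy_with(self, values: np.ndarray) -> "PopulationRaster":
        return replace(self, values=values)


@dataclass
class CategoricalRaster:
    """Integer-coded grid with a legend.

    Every non-nodata code present in ``values`` must appear in ``legend``.
    """

    values: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)
    cell_size_m: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = ""
    nodata: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype.kind not in "iu":
            raise ValidationError(
                f"categorical raster requires an integer array, got dtype {self.values.dtype}"
            )
        self.values = self.values.astype(np.int32, copy=False)
        if self.values.ndim != 2:
            raise ValidationError("categorical raster must be 2-D")
        if not self.cell_size_m > 0:
            raise ValidationError(f"cell_size_m must be positive, got {self.cell_size_m}")
        if not self.legend:
            self.legend = {int(c): str(c) for c in np.unique(self.values) if c != self.nodata}
        else:
            self.legend = {int(k): str(v) for k, v in self.legend.items()}
            present = set(int(c) for c in np.unique(self.values)) - {self.nodata}
            missing = present - set(self.legend)
            if missing:
                raise ValidationError(f"codes {sorted(missing)} present in raster but not in legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def mask_valid(self) -> np.ndarray:
        return self.values != self.nodata


@dataclass
class RaceGridSet:
    """Aligned per-group population rasters plus the total-population raster.

    The per-cell sum over groups must equal the total raster to a relative
    tolerance of 1e-6 — the defining consistency property of a set of
    dasymetric sub-population grids.
    """

    groups: tuple[str, ...]
    rasters: dict[str, PopulationRaster]
    total: PopulationRaster

    def __post_init__(self) -> None:
        self.groups = tuple(self.groups)
        if set(self.groups) != set(self.rasters):
            raise ValidationError("groups and raster keys disagree")
        assert_aligned([*self.rasters.values(), self.total])
        stack = np.stack([self.rasters[g].values for g in self.groups])
        sums = stack.sum(axis=0)
        tot = self.total.values
        inside = self.total.mask_valid()
        scale = np.maximum(np.abs(tot[inside]), 1.0)
        if not np.all(np.abs(sums[inside] - tot[inside]) <= 1e-6 * scale):
            raise ValidationError("per-cell group sums do not match the total raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.total.shape

    @property
    def cell_size_m(self) -> float:
        return self.total.cell_size_m

    def stacked(self) -> np.ndarray:
        """(n_groups, rows, cols) array in group order."""
        return np.stack([self.rasters[g].values for g in self.groups])


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------


def _geo_extratags(cell_size_m: float, origin: tuple[float, float], crs_tag: str, nodata) -> list:
    tags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(cell_size_m), float(cell_size_m), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(origin[0]), float(origin[1]), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(nodata) if not isinstance(nodata, str) else nodata),
    ]
    if crs_tag:
        tags.append((_TAG_GEO_ASCII_PARAMS, "s", 0, crs_tag))
    return tags


def _read_geo_tags(page) -> tuple[float, tuple[float, float], str, str | None]:
    cell = 30.0
    origin = (0.0, 0.0)
    crs = ""
    nodata = None
    if _TAG_MODEL_PIXEL_SCALE in page.tags:
        cell = float(page.tags[_TAG_MODEL_PIXEL_SCALE].value[0])
    if _TAG_MODEL_TIEPOINT in page.tags:
        tp = page.tags[_TAG_MODEL_TIEPOINT].value
        origin = (float(tp[3]), float(tp[4]))
    if _TAG_GEO_ASCII_PARAMS in page.tags:
        crs = str(page.tags[_TAG_GEO_ASCII_PARAMS].value).rstrip("|\x00")
    if _TAG_GDAL_NODATA in page.tags:
        nodata = str(page.tags[_TAG_GDAL_NODATA].value)
    return cell, origin, crs, nodata


def _legend_sidecar(path: Path) -> Path:
    return Path(str(path) + ".legend.json")


def write_categorical(raster: CategoricalRaster, path) -> None:
    """Write a categorical raster as an int32 single-band GeoTIFF.

    The legend is written to ``<path>.legend.json``.
    """
    path = Path(path)
    tifffile.imwrite(
        path,
        raster.values.astype(np.int32),
        extratags=_geo_extratags(raster.cell_size_m, raster.origin, raster.crs_tag, raster.nodata),
    )
    _legend_sidecar(path).write_text(
        json.dumps({str(k): v for k, v in sorted(raster.legend.items())}, indent=0)
    )


def read_categorical(path, legend: Mapping[int, str] | None = None) -> CategoricalRaster:
    """Read a single-band integer GeoTIFF as a :class:`CategoricalRaster`.

    The legend comes from, in order of precedence: the ``legend`` argument,
    a ``<path>.legend.json`` side-car, or the distinct codes in the band.

    Raises
    ------
    GridFormatError
        If the file is unreadable or the band is not of integer type.
    """
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"no such raster file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray()
            cell, origin, crs, nodata_s = _read_geo_tags(page)
    except GridFormatError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific failures
        raise GridFormatError(f"cannot read raster {path}: {exc}") from exc
    if values.ndim != 2:
        raise GridFormatError(f"{path}: expected a single-band raster, got shape {values.shape}")
    if values.dtype.kind not in "iu":
        raise GridFormatError(f"{path}: categorical raster must have an integer band, got {values.dtype}")
    nodata = int(float(nodata_s)) if nodata_s is not None else -1
    if legend is None:
        sidecar = _legend_sidecar(path)
        if sidecar.exists():
            legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    return CategoricalRaster(
        values=values, legend=dict(legend) if legend else {}, cell_size_m=cell,
        origin=origin, crs_tag=crs, nodata=nodata,
    )


def write_population(raster: PopulationRaster, path) -> None:
    """Write a population raster as a float64 single-band GeoTIFF."""
    valid = raster.values[raster.values != raster.nodata]
    if valid.size and np.nanmin(valid) < 0:
        raise ValidationError("refusing to write negative population counts")
    tifffile.imwrite(
        Path(path),
        raster.values.astype(np.float64),
        extratags=_geo_extratags(raster.cell_size_m, raster.origin, raster.crs_tag, raster.nodata),
    )


def read_population(path) -> PopulationRaster:
    """Read a single-band GeoTIFF as a :class:`PopulationRaster`."""
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"no such raster file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray()
            cell, origin, crs, nodata_s = _read_geo_tags(page)
    except Exception as exc:
        raise GridFormatError(f"cannot read raster {path}: {exc}") from exc
    if values.ndim != 2:
        raise GridFormatError(f"{path}: expected a single-band raster, got shape {values.shape}")
    nodata = float(nodata_s) if nodata_s is not None else -1.0
    return PopulationRaster(
        values=np.asarray(values, dtype=np.float64), cell_size_m=cell,
        origin=origin, crs_tag=crs, nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Unit conversions and alignment
# ---------------------------------------------------------------------------


def counts_to_density(raster: PopulationRaster) -> PopulationRaster:
    """Convert people/cell to people/km^2 (factor 10^6 / cell_size_m^2).

    nodata cells are propagated unchanged.
    """
    factor = 1e6 / raster.cell_size_m**2
    out = raster.values * factor
    out[raster.values == raster.nodata] = raster.nodata
    return raster.copy_with(out)


def density_to_counts(raster: PopulationRaster) -> PopulationRaster:
    """Inverse of :func:`counts_to_density`."""
    factor = raster.cell_size_m**2 / 1e6
    out = raster.values * factor
    out[raster.values == raster.nodata] = raster.nodata
    return raster.copy_with(out)


def assert_aligned(rasters: Sequence) -> None:
    """Check that all rasters share shape, cell size, and origin.

    Raises
    ------
    AlignmentError
        Naming the first raster (by position) that disagrees with the first.
    """
    if len(rasters) < 2:
        return
    ref = rasters[0]
    for i, r in enumerate(rasters[1:], start=1):
        if r.shape != ref.shape:
            raise AlignmentError(f"raster #{i}: shape {r.shape} != {ref.shape}")
        if not np.isclose(r.cell_size_m, ref.cell_size_m):
            raise AlignmentError(f"raster #{i}: cell size {r.cell_size_m} != {ref.cell_size_m}")
        if not np.allclose(r.origin, ref.origin):
            raise AlignmentError(f"raster #{i}: origin {r.origin} != {ref.origin}")
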