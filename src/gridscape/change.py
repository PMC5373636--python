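"""Temporal change analysis: transition matrices and percent-change reports.

Because the grids of different census years share the same geometry, change
can be assessed cell by cell.  A transition matrix cross-tabulates the
community label of every cell in year 1 against its label in year 2 — in
cells, and optionally in people, by weighting each cell with a population
raster (year-1 population by default: who lived under the old label).

Percent changes are reported as the nearest integer, rounding halves away
from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid_io import CategoricalRaster, PopulationRaster, assert_aligned
from .diversity import N_INHABITED

__all__ = ["TransitionMatrix", "transition_matrix", "percent_change", "change_report"]


@dataclass
class TransitionMatrix:
    """Label-by-label cross-tabulation between two years.

    ``cells[r, c]`` counts cells labelled ``r`` in year 1 and ``c`` in
    year 2; ``people`` is the same tabulation weighted by a population
    raster (or None).  Row sums equal the year-1 label histogram, column
    sums the year-2 histogram; the cell total equals the grid size.
    """

    cells: pd.DataFrame
    people: pd.DataFrame | None
    year1: str = "year1"
    year2: str = "year2"

    @property
    def labels(self) -> np.ndarray:
        return self.cells.index.to_numpy()


def transition_matrix(
    map1: CategoricalRaster,
    map2: CategoricalRaster,
    pop: PopulationRaster | None = None,
    n_labels: int = N_INHABITED + 1,
    year1: str = "year1",
    year2: str = "year2",
) -> TransitionMatrix:
    """Cross-tabulate labels of two aligned diversity maps over all cells.

    nodata cells are tallied as code 0 (uninhabited): outside-study-area
    cells are a real transition class when coverage changes.
    """
    rasters = [map1, map2] + ([pop] if pop is not None else [])
    assert_aligned(rasters)
    v1 = np.where(map1.values == map1.nodata, 0, map1.values).ravel()
    v2 = np.where(map2.values == map2.nodata, 0, map2.values).ravel()
    if v1.min() < 0 or v1.max() >= n_labels or v2.min() < 0 or v2.max() >= n_labels:
        raise ValidationError(f"labels outside 0..{n_labels - 1}")
    flat = v1.astype(np.int64) * n_labels + v2
    counts = np.bincount(flat, minlength=n_labels * n_labels).reshape(n_labels, n_labels)
    labels = np.arange(n_labels)
    cells = pd.DataFrame(counts, index=labels, columns=labels)
    people = None
    if pop is not None:
        w = np.where(pop.mask_valid(), pop.values, 0.0).ravel()
        pcounts = np.bincount(flat, weights=w, minlength=n_labels * n_labels)
        people = pd.DataFrame(pcounts.reshape(n_labels, n_labels), index=labels, columns=labels)
    return TransitionMatrix(cells=cells, people=people, year1=year1, year2=year2)


def percent_change(old: float, new: float) -> float:
    """Signed percent change, rounded to the nearest integer (half away from zero).

    Undefined (NaN) when ``old`` is 0.
    """
    if old == 0 or not np.isfinite(old) or not np.isfinite(new):
        return float("nan")
    pct = 100.0 * (new - old) / old
    return float(math.copysign(math.floor(abs(pct) + 0.5), pct))


def change_report(reports: list[tuple[str, pd.Series]]) -> pd.DataFrame:
    """Tabulate metric values by year with percent changes vs. the previous year.

    ``reports`` is a list of ``(year, metric -> value)`` pairs sharing one
    metric set.  Output is indexed by metric with a value column per year
    and a ``change_<year>`` column (NaN for the first year / undefined).
    """
    if len(reports) < 2:
        raise ValidationError("change report needs at least 2 years")
    years = [y for y, _ in reports]
    series = [pd.Series(s, dtype=float) for _, s in reports]
    base = set(series[0].index)
    for y, s in zip(years[1:], series[1:]):
        if set(s.index) != base:
            raise ValidationError(f"metric set for {y} differs from {years[0]}")
    out = pd.DataFrame(index=series[0].index)
    for y, s in zip(years, series):
        out[str(y)] = s
    for prev, (y, s) in zip(series, list(zip(years, series))[1:]):
        out[f"change_{y}"] = [
            percent_change(prev[mname], s[mname]) for mname in out.index
        ]
    return out
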