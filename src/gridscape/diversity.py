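"""Classification of population grids into diversity/dominant-group/density communities.

Each grid cell carries densities for six race/ethnicity groups (NHAS and
NHPI are combined, as in the 1990 census tabulation): NHW, NHB, NHAS+NHPI,
NHAM, NHO, H.  A cell with zero total population is *uninhabited* (code 0).
Every inhabited cell receives one of 39 community labels built from three
discriminants:

* **dominant group** — the group with the largest density (ties go to the
  first group in the fixed order above);
* **diversity** — from the standardized Shannon entropy ``E`` of the group
  shares (normalized by ln 6, so E in [0, 1]) together with the dominant
  share: *low* iff ``E < 0.37`` and share ``> 80%``; *high* iff ``E > 0.73``
  and share ``< 50%``; otherwise *medium*.  High-diversity cells carry no
  dominant group;
* **density** — total density in people/km^2: *low* ``< 3``, *medium*
  ``3–30`` (boundaries inclusive), *high* ``> 30``.

That yields (6 groups x {low, medium} diversity + high diversity) x 3
density classes = 39 inhabited labels.  Dropping the density discriminant
collapses them to 13 diversity/dominant-group categories (+ uninhabited).

Code numbering (documented here and in the emitted legend; the published
data product uses its own, unprinted encoding): code 0 is uninhabited;
codes 1–39 are ordered by density class (low, medium, high), and within a
density class by (NHW low, NHW medium, NHB low, NHB medium, ..., H low,
H medium, high-diversity).  So codes 1–13 are low density, 14–26 medium,
27–39 high, and ``(code - 1) % 13 + 1`` is the collapsed code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError
from .grid_io import CategoricalRaster, RaceGridSet

__all__ = [
    "GROUPS_6",
    "ClassifierParams",
    "CommunityLabel",
    "merge_groups",
    "merge_grid_set",
    "standardized_entropy",
    "density_class",
    "classify_cell",
    "classify_map",
    "collapse_density",
    "full_legend",
    "legend_table",
    "label_components",
    "N_INHABITED",
    "N_COLLAPSED",
]

#: Six-group order after merging NHAS and NHPI.
GROUPS_6 = ("NHW", "NHB", "NHAS_NHPI", "NHAM", "NHO", "H")

_DIVERSITY_NAMES = ("low", "medium", "high")
_DENSITY_NAMES = ("low", "medium", "high")

#: The 13 collapsed (diversity x dominant group) categories, in code order.
COLLAPSED_CATEGORIES: tuple[tuple[str | None, str], ...] = tuple(
    (g, d) for g in GROUPS_6 for d in ("low", "medium")
) + ((None, "high"),)

N_COLLAPSED = len(COLLAPSED_CATEGORIES)  # 13
N_INHABITED = N_COLLAPSED * 3  # 39


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the community classifier.

    Defaults are the published scheme; they can be overridden for
    sensitivity analysis.  All comparisons against ``entropy_*`` and
    ``share_*`` are strict; the density boundaries 3 and 30 people/km^2
    both fall in the medium class.
    """

    entropy_low: float = 0.37
    entropy_high: float = 0.73
    share_low: float = 0.80  # dominant share must EXCEED this for low diversity
    share_high: float = 0.50  # dominant share must be BELOW this for high diversity
    density_low: float = 3.0  # people/km^2
    density_high: float = 30.0


DEFAULT_PARAMS = ClassifierParams()


@dataclass(frozen=True)
class CommunityLabel:
    """Decoded community label: code plus its three discriminants."""

    code: int
    dominant: str | None  # None iff diversity == "high" or code == 0
    diversity: str | None  # None iff code == 0
    density: str | None  # None iff code == 0

    @property
    def uninhabited(self) -> bool:
        return self.code == 0


def _compose_code(collapsed_idx: int, density_idx: int) -> int:
    return density_idx * N_COLLAPSED + collapsed_idx + 1


def label_components(code: int) -> CommunityLabel:
    """Decode an integer label into its discriminants."""
    if code == 0:
        return CommunityLabel(0, None, None, None)
    if not 1 <= code <= N_INHABITED:
        raise ValidationError(f"unknown community code {code}")
    density_idx, collapsed_idx = divmod(code - 1, N_COLLAPSED)
    dominant, diversity = COLLAPSED_CATEGORIES[collapsed_idx]
    return CommunityLabel(code, dominant, diversity, _DENSITY_NAMES[density_idx])


def full_legend() -> dict[int, str]:
    """Legend for all 40 codes, e.g. ``17 -> 'NHB/medium-div/medium-dens'``."""
    legend = {0: "uninhabited"}
    for code in range(1, N_INHABITED + 1):
        lab = label_components(code)
        dom = lab.dominant if lab.dominant is not None else "mixed"
        legend[code] = f"{dom}/{lab.diversity}-div/{lab.density}-dens"
    return legend


def _label_color(lab: CommunityLabel) -> str:
    """Fixed colormap: hue by dominant group, saturation by diversity, lightness by density."""
    import colorsys

    if lab.code == 0:
        return "#ffffff"
    hues = {"NHW": 0.08, "NHB": 0.33, "NHAS_NHPI": 0.0, "NHAM": 0.55, "NHO": 0.12, "H": 0.78}
    hue = hues.get(lab.dominant, 0.62) if lab.dominant else 0.62
    sat = {"low": 0.95, "medium": 0.55, "high": 0.35}[lab.diversity]
    light = {"low": 0.80, "medium": 0.60, "high": 0.40}[lab.density]
    r, g, b = colorsys.hls_to_rgb(hue, light, sat)
    return "#{:02x}{:02x}{:02x}".format(int(r * 255), int(g * 255), int(b * 255))


def legend_table() -> pd.DataFrame:
    """Legend as a DataFrame with columns code, dominant, diversity, density, color."""
    rows = []
    for code in range(0, N_INHABITED + 1):
        lab = label_components(code)
        rows.append(
            {
                "code": code,
                "dominant": lab.dominant or ("" if code == 0 else "mixed"),
                "diversity": lab.diversity or "",
                "density": lab.density or "",
                "color": _label_color(lab),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-cell pieces
# ---------------------------------------------------------------------------


def merge_groups(seven: Sequence[float]) -> np.ndarray:
    """Merge a 7-group composition (NHW, NHB, NHAS, NHAM, NHPI, NHO, H) to 6.

    NHAS and NHPI are summed; the total is preserved.
    """
    v = np.asarray(seven, dtype=np.float64)
    if v.shape[-1] != 7:
        raise ValidationError(f"expected 7 components, got {v.shape[-1]}")
    if np.any(v < 0):
        raise ValidationError("composition components must be non-negative")
    # order in: NHW, NHB, NHAS, NHAM, NHPI, NHO, H -> out: NHW, NHB, NHAS+NHPI, NHAM, NHO, H
    out = np.stack(
        [v[..., 0], v[..., 1], v[..., 2] + v[..., 4], v[..., 3], v[..., 5], v[..., 6]],
        axis=-1,
    )
    return out


def merge_grid_set(grids: RaceGridSet) -> np.ndarray:
    """(6, rows, cols) density stack in GROUPS_6 order from a 7-group grid set.

    nodata cells are zeroed (treated as uninhabited downstream).
    """
    arr = {g: np.where(r.mask_valid(), r.values, 0.0) for g, r in grids.rasters.items()}
    try:
        stack = np.stack(
            [
                arr["NHW"],
                arr["NHB"],
                arr["NHAS"] + arr["NHPI"],
                arr["NHAM"],
                arr["NHO"],
                arr["H"],
            ]
        )
    except KeyError as exc:
        raise ValidationError(f"grid set lacks group {exc}") from exc
    return stack


def standardized_entropy(d: Sequence[float]) -> float:
    """Standardized Shannon entropy of a composition, in [0, 1].

    ``E = -sum p_i ln p_i / ln 6`` with ``p_i = d_i / total`` and the
    convention ``0 ln 0 = 0``.  Invariant to rescaling all densities.
    """
    v = np.asarray(d, dtype=np.float64)
    if np.any(v < 0):
        raise ValidationError("densities must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValidationError("standardized entropy undefined for zero total")
    p = v / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() / np.log(len(v)))


def density_class(total_density: float, params: ClassifierParams = DEFAULT_PARAMS) -> str:
    """Classify a positive total density (people/km^2) as low/medium/high."""
    if not total_density > 0:
        raise ValidationError("density class requires a positive density")
    if total_density < params.density_low:
        return "low"
    if total_density <= params.density_high:
        return "medium"
    return "high"


def classify_cell(
    d: Sequence[float], cell_size_m: float, params: ClassifierParams = DEFAULT_PARAMS
) -> CommunityLabel:
    """Classify one cell from its 6-group people/cell composition."""
    v = np.asarray(d, dtype=np.float64)
    if v.shape != (6,):
        raise ValidationError(f"expected a 6-group composition, got shape {v.shape}")
    if np.any(v < 0):
        raise ValidationError("densities must be non-negative")
    total = v.sum()
    if total == 0:
        return label_components(0)
    dom_idx = int(np.argmax(v))  # argmax ties -> first group in fixed order
    share = v[dom_idx] / total
    e = standardized_entropy(v)
    if e < params.entropy_low and share > params.share_low:
        diversity = "low"
    elif e > params.entropy_high and share < params.share_high:
        diversity = "high"
    else:
        diversity = "medium"
    dens_km2 = total * 1e6 / cell_size_m**2
    dens = density_class(dens_km2, params)
    if diversity == "high":
        collapsed_idx = N_COLLAPSED - 1
    else:
        collapsed_idx = dom_idx * 2 + (0 if diversity == "low" else 1)
    return label_components(_compose_code(collapsed_idx, _DENSITY_NAMES.index(dens)))


# ---------------------------------------------------------------------------
# Whole-map operations (vectorized)
# ---------------------------------------------------------------------------


def classify_map(
    grids: RaceGridSet, params: ClassifierParams = DEFAULT_PARAMS
) -> CategoricalRaster:
    """Cell-wise classification of a 7-group grid set into the 40-label map.

    Cells outside the study area (total == nodata) classify as code 0, like
    any other zero-population cell; downstream landscape analysis excludes
    code 0 from the landscape either way.
    """
    stack = merge_grid_set(grids)  # (6, r, c), nodata zeroed
    total = stack.sum(axis=0)
    out = np.zeros(total.shape, dtype=np.int32)
    inhab = total > 0
    if inhab.any():
        sub = stack[:, inhab]  # (6, n)
        tot = total[inhab]
        p = sub / tot
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e = -plogp.sum(axis=0) / np.log(6.0)
        dom_idx = np.argmax(sub, axis=0)
        share = np.take_along_axis(sub, dom_idx[None, :], axis=0)[0] / tot
        low = (e < params.entropy_low) & (share > params.share_low)
        high = (e > params.entropy_high) & (share < params.share_high)
        dens_km2 = tot * 1e6 / grids.cell_size_m**2
        dens_idx = np.where(
            dens_km2 < params.density_low, 0, np.where(dens_km2 <= params.density_high, 1, 2)
        )
        collapsed_idx = np.where(
            high, N_COLLAPSED - 1, dom_idx * 2 + np.where(low, 0, 1)
        )
        out[inhab] = dens_idx * N_COLLAPSED + collapsed_idx + 1
    return CategoricalRaster(
        values=out,
        legend=full_legend(),
        cell_size_m=grids.cell_size_m,
        origin=grids.total.origin,
        crs_tag=grids.total.crs_tag,
        nodata=-1,
    )


def collapse_density(div_map: CategoricalRaster) -> CategoricalRaster:
    """Collapse the 40-label map to 13 diversity/dominant categories + uninhabited.

    The three density variants of each category map to one code via
    ``(code - 1) % 13 + 1``; code 0 is unchanged.  Idempotent.
    """
    vals = div_map.values
    known = (vals >= 0) & (vals <= N_INHABITED) | (vals == div_map.nodata)
    if not known.all():
        bad = np.unique(vals[~known])
        raise ValidationError(f"unknown community codes {bad.tolist()[:5]}")
    out = np.where(vals > 0, (vals - 1) % N_COLLAPSED + 1, vals).astype(np.int32)
    legend = {0: "uninhabited"}
    for idx, (dom, div) in enumerate(COLLAPSED_CATEGORIES):
        legend[idx + 1] = f"{dom or 'mixed'}/{div}-div"
    return CategoricalRaster(
        values=out,
        legend=legend,
        cell_size_m=div_map.cell_size_m,
        origin=div_map.origin,
        crs_tag=div_map.crs_tag,
        nodata=div_map.nodata,
    )
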