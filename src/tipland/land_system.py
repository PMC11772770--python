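"""Land-system construction from categorical land-cover grids.

A land *cover* grid holds one of ten basic cover types per fine cell
(cropland, forest, grassland, shrubland, wetland, water body, tundra,
artificial surfaces, bare land, snow/ice; integer codes 0-9). A land
*system* grid is a coarser categorical raster whose legend crosses the
dominant cover type with a within-cell density level (low/medium/high),
giving up to 30 classes, coded type-major::

    code = 3 * cover_type + density          density: 0=L, 1=M, 2=H

Construction proceeds in three steps: block-majority upscaling (the dominant
type and its area fraction per non-overlapping window), natural-breaks
classification of the dominant fractions into three density levels per cover
type, and the cross product of the two. Density levels can be merged back
(``code // 3``) to validate at the ten-class thematic resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import GridError, Raster, check_aligned

log = logging.getLogger(__name__)

COVER_NAMES = (
    "cropland",
    "forest",
    "grassland",
    "shrubland",
    "wetland",
    "water",
    "tundra",
    "artificial",
    "bare",
    "snow_ice",
)
N_COVER_TYPES = len(COVER_NAMES)
DENSITY_NAMES = ("L", "M", "H")
N_LAND_SYSTEM_CLASSES = N_COVER_TYPES * len(DENSITY_NAMES)

#: Land-system legend, code -> name (e.g. 5 -> "forest_H").
LAND_SYSTEM_LEGEND = {
    3 * t + d: f"{COVER_NAMES[t]}_{DENSITY_NAMES[d]}"
    for t in range(N_COVER_TYPES)
    for d in range(3)
}


@dataclass
class DensityBreaks:
    """Two natural-break points per cover type on the dominant-fraction scale.

    Intervals are left-inclusive at the breaks: fraction <= b1 is low,
    b1 < fraction <= b2 medium, fraction > b2 high. Types with fewer than
    three distinct fraction values are degenerate: all their cells are
    assigned high density and the condition is flagged.
    """

    breaks: dict[int, tuple[float, float]] = field(default_factory=dict)
    degenerate: set[int] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "breaks": {str(t): list(b) for t, b in self.breaks.items()},
            "degenerate": sorted(self.degenerate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DensityBreaks":
        return cls(
            breaks={int(t): tuple(b) for t, b in d.get("breaks", {}).items()},
            degenerate=set(d.get("degenerate", [])),
        )


def upscale_dominant_type(
    cover: Raster, window: int, min_block_fraction: float = 0.5
) -> tuple[Raster, Raster]:
    """Block-majority upscaling of a categorical cover raster.

    Slides a non-overlapping ``window x window`` block over the raster and
    returns the modal (dominant) cover class per block together with its
    area fraction among the block's valid cells. Edge-truncated blocks are
    kept only if at least ``min_block_fraction`` of the full block lies
    inside the raster; modal ties resolve to the lowest class code.

    Returns ``(type_grid, fraction_grid)`` at cell size
    ``window * cover.cell_size``; all-nodata blocks become nodata.
    """
    if window < 1:
        raise GridError(f"window must be >= 1, got {window}")
    nrow, ncol = cover.shape
    if nrow < window or ncol < window:
        raise GridError(
            f"raster {cover.shape} smaller than window {window}"
        )

    def n_blocks(n: int) -> int:
        full, rem = divmod(n, window)
        # keep the truncated trailing block if it covers >= the cutoff share
        return full + (1 if rem and rem / window >= min_block_fraction else 0)

    out_r, out_c = n_blocks(nrow), n_blocks(ncol)
    nodata_out = -1 if cover.nodata is None else int(cover.nodata)
    type_vals = np.full((out_r, out_c), nodata_out, dtype=np.int16)
    frac_vals = np.full((out_r, out_c), np.nan, dtype=np.float64)

    values = cover.values
    valid = cover.valid_mask()
    for br in range(out_r):
        r0, r1 = br * window, min((br + 1) * window, nrow)
        for bc in range(out_c):
            c0, c1 = bc * window, min((bc + 1) * window, ncol)
            block = values[r0:r1, c0:c1]
            bvalid = valid[r0:r1, c0:c1]
            n_valid = int(bvalid.sum())
            if n_valid == 0:
                continue
            counts = np.bincount(block[bvalid].astype(np.int64))
            modal = int(counts.argmax())  # argmax takes lowest code on ties
            type_vals[br, bc] = modal
            frac_vals[br, bc] = counts[modal] / n_valid

    coarse_size = window * cover.cell_size
    type_grid = Raster(type_vals, coarse_size, nodata=nodata_out, origin=cover.origin)
    frac_grid = Raster(frac_vals, coarse_size, nodata=None, origin=cover.origin)
    return type_grid, frac_grid


def jenks_breaks(values: np.ndarray, n_classes: int = 3) -> np.ndarray:
    """Exact natural-breaks (minimum within-class SSD) partition of 1-D data.

    Returns the upper bound (maximum) of each of the first ``n_classes - 1``
    classes over the globally optimal contiguous partition of the sorted
    values. Exact via prefix-sum enumeration of all split pairs; ties go to
    the first (lowest-split) optimum.
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    if n < n_classes:
        raise GridError(f"need >= {n_classes} values, got {n}")
    if n_classes != 3:
        raise NotImplementedError("only the three-class split is used here")

    # SSD of x[i:j] from prefix sums: S2 - S1^2 / m
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: np.ndarray, j: np.ndarray) -> np.ndarray:
        m = j - i
        s1 = c1[j] - c1[i]
        s2 = c2[j] - c2[i]
        return s2 - s1 * s1 / m

    # splits: class1 = x[:i], class2 = x[i:j], class3 = x[j:], 1<=i<j<=n-1
    i = np.arange(1, n - 1)
    best_cost = np.inf
    best = (1, 2)
    left = ssd(np.zeros_like(i), i)
    for k, ii in enumerate(i):
        j = np.arange(ii + 1, n)
        cost = left[k] + ssd(np.full_like(j, ii), j) + ssd(j, np.full_like(j, n))
        jbest = int(cost.argmin())
        if cost[jbest] < best_cost - 1e-15:
            best_cost = float(cost[jbest])
            best = (int(ii), int(j[jbest]))
    i1, i2 = best
    return np.array([x[i1 - 1], x[i2 - 1]])


def compute_density_breaks(
    fractions_by_type: dict[int, np.ndarray]
) -> DensityBreaks:
    """Natural-breaks density breakpoints per cover type.

    Each type's collection of dominant-fraction values is split into three
    classes (low/medium/high, ascending) minimizing within-class sum of
    squared deviations; the two breakpoints are the maxima of the low and
    medium classes. Types with fewer than three distinct values are flagged
    degenerate.
    """
    result = DensityBreaks()
    for t, fracs in fractions_by_type.items():
        fracs = np.asarray(fracs, dtype=np.float64)
        if fracs.size == 0:
            raise GridError(f"empty fraction collection for type {t}")
        if np.unique(fracs).size < 3:
            result.degenerate.add(t)
            log.warning(
                "cover type %s has <3 distinct dominant fractions; "
                "density degenerate (all high)", t,
            )
            continue
        b1, b2 = jenks_breaks(fracs, 3)
        result.breaks[t] = (float(b1), float(b2))
    return result


def fractions_by_type(type_grid: Raster, fraction_grid: Raster) -> dict[int, np.ndarray]:
    """Collect each cover type's dominant fractions from an upscaled pair."""
    check_aligned(type_grid, fraction_grid)
    valid = type_grid.valid_mask() & ~np.isnan(fraction_grid.values)
    out: dict[int, np.ndarray] = {}
    for t in np.unique(type_grid.values[valid]):
        out[int(t)] = fraction_grid.values[valid & (type_grid.values == t)]
    return out


def classify_density(
    type_grid: Raster, fraction_grid: Raster, breaks: DensityBreaks
) -> Raster:
    """Cross dominant type with density level into land-system codes 0..29."""
    check_aligned(type_grid, fraction_grid)
    nodata = -1 if type_grid.nodata is None else int(type_grid.nodata)
    out = np.full(type_grid.shape, nodata, dtype=np.int16)
    valid = type_grid.valid_mask()
    present = set(int(t) for t in np.unique(type_grid.values[valid]))
    missing = present - set(breaks.breaks) - breaks.degenerate
    if missing:
        raise GridError(f"no density breaks for cover types {sorted(missing)}")
    for t in present:
        sel = valid & (type_grid.values == t)
        if t in breaks.degenerate:
            out[sel] = 3 * t + 2  # all high per the degenerate rule
            continue
        b1, b2 = breaks.breaks[t]
        f = fraction_grid.values
        density = np.where(f <= b1, 0, np.where(f <= b2, 1, 2))
        out[sel] = 3 * t + density[sel]
    return type_grid.with_values(out, nodata=nodata)


def build_land_system(
    cover: Raster, window: int
) -> tuple[Raster, DensityBreaks]:
    """Convenience: cover -> (land-system grid, density breaks) in one call."""
    type_grid, frac_grid = upscale_dominant_type(cover, window)
    breaks = compute_density_breaks(fractions_by_type(type_grid, frac_grid))
    return classify_density(type_grid, frac_grid, breaks), breaks


def resample_nearest(grid: Raster, target_cell_size: float) -> Raster:
    """Nearest-neighbour resampling to a new cell size.

    Each output cell takes the value of the input cell whose centre is
    nearest to its own centre; no new values are introduced.
    """
    if not target_cell_size > 0:
        raise GridError(f"target cell size must be positive, got {target_cell_size}")
    if np.isclose(target_cell_size, grid.cell_size):
        return grid.with_values(grid.values.copy())
    nrow, ncol = grid.shape
    out_r = max(1, int(round(nrow * grid.cell_size / target_cell_size)))
    out_c = max(1, int(round(ncol * grid.cell_size / target_cell_size)))
    # centre of output cell k is (k + 0.5) * target; the nearest input centre
    # index is floor(centre / input_size), clipped at the edges
    rows = np.clip(
        np.floor((np.arange(out_r) + 0.5) * target_cell_size / grid.cell_size),
        0, nrow - 1,
    ).astype(int)
    cols = np.clip(
        np.floor((np.arange(out_c) + 0.5) * target_cell_size / grid.cell_size),
        0, ncol - 1,
    ).astype(int)
    return Raster(
        grid.values[np.ix_(rows, cols)],
        target_cell_size,
        nodata=grid.nodata,
        origin=grid.origin,
    )


def merge_density(ls: Raster) -> Raster:
    """Collapse density levels: land-system code -> cover type (code // 3)."""
    values = ls.values
    bad = ls.valid_mask() & ((values < 0) | (values >= N_LAND_SYSTEM_CLASSES))
    if bad.any():
        raise GridError(
            f"invalid land-system codes: {sorted(np.unique(values[bad]).tolist())}"
        )
    out = np.where(ls.valid_mask(), values // 3, values)
    return ls.with_values(out.astype(values.dtype))
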