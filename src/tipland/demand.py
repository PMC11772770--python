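"""Service demand and supply capacity.

The demand side harmonizes integrated-assessment-model (IAM) land-area
tables — rows of (basin, land_type, year, area) — into per-basin demand for
four land-system *services*: cropland, forest, grassland and shrubland area.
Each IAM land type either maps to one service, is on a fixed exclusion list
of types treated as unchanging (tundra, urban, rocky, snow/ice, desert), or
is rejected as unknown.

The supply side gives every land-system class a capacity vector CA[j, d]:
the area (km² per coarse cell) of service d that one cell of class j
provides, estimated as the mean area of the service's backing cover type
among the fine cells nested inside coarse cells of class j. A class can
supply several services and a service can come from several classes.

All areas are handled internally in km²; the IAM reader converts on ingest
from a declared unit (``km2`` or ``thous_km2``).
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .grids import GeometryError, GridError, Raster, check_aligned
from .land_system import N_COVER_TYPES, N_LAND_SYSTEM_CLASSES

log = logging.getLogger(__name__)

SERVICES = ("cropland", "forest", "grassland", "shrubland")
N_SERVICES = len(SERVICES)
#: cover-type code backing each service (type-major legend order)
SERVICE_COVER_CODE = {"cropland": 0, "forest": 1, "grassland": 2, "shrubland": 3}

_UNIT_TO_KM2 = {"km2": 1.0, "thous_km2": 1000.0}


class UnknownLandTypeError(ValueError):
    """IAM land types that neither map to a service nor are excluded."""


def load_service_mapping(path=None) -> dict:
    """Load the land-type -> service dictionary (package default or a file).

    Returns ``{"map": {lowercased type: service}, "excluded": set of
    lowercased types}``. The "forestland" spelling is normalized to the
    single service key ``forest``.
    """
    if path is None:
        text = resources.files("tipland.data").joinpath("service_mapping.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    mapping: dict[str, str] = {}
    for service, types in raw["services"].items():
        service = "forest" if service.lower() in ("forestland", "forest") else service.lower()
        if service not in SERVICES:
            raise ValueError(f"unknown service key in mapping: {service}")
        for t in types:
            mapping[t.strip().lower()] = service
    excluded = {t.strip().lower() for t in raw.get("excluded", [])}
    return {"map": mapping, "excluded": excluded}


def reclassify_iam_types(
    records: pd.DataFrame, mapping: dict | None = None
) -> pd.DataFrame:
    """Annotate IAM records with service labels; drop excluded types.

    ``records`` needs columns basin, land_type, year, area and optionally
    unit (km2 | thous_km2, default km2). Areas are converted to km². Unknown
    land types raise :class:`UnknownLandTypeError` listing them.
    """
    mapping = mapping or load_service_mapping()
    df = records.copy()
    key = df["land_type"].astype(str).str.strip().str.lower()
    service = key.map(mapping["map"])
    excluded = key.isin(mapping["excluded"])
    unknown = sorted(key[service.isna() & ~excluded].unique())
    if unknown:
        raise UnknownLandTypeError(f"unknown IAM land types: {unknown}")
    if excluded.any():
        log.info(
            "dropped %d records of excluded land types: %s",
            int(excluded.sum()), sorted(key[excluded].unique()),
        )
    df["service"] = service
    df = df[~excluded].copy()
    if (df["area"] < 0).any():
        raise ValueError("negative areas in IAM records")
    if "unit" in df.columns:
        factor = df["unit"].map(_UNIT_TO_KM2)
        if factor.isna().any():
            bad = sorted(df.loc[factor.isna(), "unit"].unique())
            raise ValueError(f"unknown area units: {bad}")
        df["area"] = df["area"] * factor
        df = df.drop(columns="unit")
    return df


def aggregate_service_demand(
    records: pd.DataFrame, basin, year: int
) -> dict[str, float]:
    """Total area (km²) demanded per service for one basin and year.

    ``records`` must already carry the ``service`` column from
    :func:`reclassify_iam_types`. Services with no records get demand 0
    (with a warning).
    """
    sel = records[(records["basin"] == basin) & (records["year"] == year)]
    totals = sel.groupby("service")["area"].sum()
    demand = {}
    for d in SERVICES:
        if d in totals.index:
            demand[d] = float(totals[d])
        else:
            log.warning("no %s records for basin=%s year=%s; demand 0", d, basin, year)
            demand[d] = 0.0
    return demand


def _nesting_window(cover: Raster, ls: Raster) -> int:
    ratio = ls.cell_size / cover.cell_size
    window = int(round(ratio))
    if not np.isclose(ratio, window) or window < 1:
        raise GeometryError(
            f"land-system cells ({ls.cell_size} m) do not nest an integer "
            f"block of cover cells ({cover.cell_size} m)"
        )
    nr, nc = ls.shape
    if cover.shape[0] < nr * window or cover.shape[1] < nc * window:
        raise GeometryError(
            f"cover {cover.shape} too small for {ls.shape} blocks of {window}"
        )
    return window


def _service_counts_per_block(cover: Raster, ls: Raster) -> np.ndarray:
    """(nrow, ncol, N_SERVICES) counts of service-backing fine cells per block."""
    window = _nesting_window(cover, ls)
    nr, nc = ls.shape
    fine = cover.values[: nr * window, : nc * window]
    valid = cover.valid_mask()[: nr * window, : nc * window]
    blocks = fine.reshape(nr, window, nc, window).swapaxes(1, 2)
    bvalid = valid.reshape(nr, window, nc, window).swapaxes(1, 2)
    counts = np.empty((nr, nc, N_SERVICES), dtype=np.int64)
    for d, name in enumerate(SERVICES):
        code = SERVICE_COVER_CODE[name]
        counts[:, :, d] = ((blocks == code) & bvalid).sum(axis=(2, 3))
    return counts


def compute_supply_capacity(cover: Raster, ls: Raster) -> np.ndarray:
    """Supply-capacity matrix CA[j, d] in km² per coarse cell.

    For each land-system class j, CA[j, d] is the mean, over coarse cells of
    class j, of (fine cells of service d's backing cover type inside the
    cell) x (fine-cell area). Classes absent from ``ls`` get all-zero rows;
    non-service cover types implicitly supply nothing.
    """
    counts = _service_counts_per_block(cover, ls)
    fine_area_km2 = (cover.cell_size / 1000.0) ** 2
    ca = np.zeros((N_LAND_SYSTEM_CLASSES, N_SERVICES))
    valid = ls.valid_mask()
    for j in np.unique(ls.values[valid]):
        sel = valid & (ls.values == j)
        ca[int(j)] = counts[sel].mean(axis=0) * fine_area_km2
    return ca


def demand_from_landcover(cover: Raster, mask: Raster) -> dict[str, float]:
    """Historical-validation demand: total backing-cover area inside a mask.

    Used when validating against an observed end-year map instead of IAM
    scenario tables; the demand for each service is simply the area of its
    backing cover type within the (nonzero) mask.
    """
    check_aligned(cover, mask)
    inside = (mask.values != 0) & mask.valid_mask() & cover.valid_mask()
    if not inside.any():
        raise GridError("empty region mask")
    fine_area_km2 = (cover.cell_size / 1000.0) ** 2
    return {
        d: float(((cover.values == SERVICE_COVER_CODE[d]) & inside).sum())
        * fine_area_km2
        for d in SERVICES
    }


def supply_from_grid(ls: Raster, ca: np.ndarray) -> np.ndarray:
    """Current supply per service implied by a land-system grid and CA."""
    valid = ls.valid_mask()
    counts = np.bincount(
        ls.values[valid].astype(np.int64), minlength=N_LAND_SYSTEM_CLASSES
    )
    return counts @ ca
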