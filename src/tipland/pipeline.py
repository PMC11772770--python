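"""End-to-end orchestration of the four-part toolchain.

A single validated configuration drives: (1) land-system construction from
a cover raster, (2) demand harmonization and supply-capacity estimation,
(3) suitability modelling, and (4) demand-driven allocation plus
validation. On synthetic mode the scene, drivers and the observed later map
are generated from the config's seed, the simulation is run from the
earlier map toward the later map's demand, and the result is scored with
kappa and the figure of merit at 30- and 10-class thematic resolution —
the same historical-validation design used with real observed map pairs.

Every stage's parameters and seeds land in a run-metadata JSON; re-running
the same config reproduces identical artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allocation import (
    AllocationConfig,
    allocate,
    derive_conversion_matrix,
    estimate_resistance,
    interpolate_demand,
)
from .demand import SERVICES, compute_supply_capacity, demand_from_landcover, supply_from_grid
from .grids import GridError, Raster, write_raster
from .land_system import (
    classify_density,
    compute_density_breaks,
    fractions_by_type,
    merge_density,
    upscale_dominant_type,
)
from .suitability import (
    build_training_samples,
    compute_density_drivers,
    fit_suitability_model,
    predict_suitability,
)
from .synthetic import (
    SceneSpec,
    TransitionRule,
    generate_drivers,
    generate_landscape,
    generate_transition_pair,
)
from .validation import Undefined, validation_report

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 1,
    "scene": {
        "shape": [300, 300],
        "correlation_length": 3.0,
        "cell_size": 30.0,
    },
    "window": 5,
    "rules": [
        # forest -> cropland pushed by the cropland-linked driver
        {"from_class": 1, "to_class": 0, "prob": 0.25, "driver": "signal_0"},
        {"from_class": 2, "to_class": 0, "prob": 0.15, "driver": "signal_0"},
        {"from_class": 3, "to_class": 2, "prob": 0.10},
    ],
    "suitability": {
        "target": "loss",
        "n_trees": 200,
        "sample_fraction": 0.25,
        "balanced": False,
    },
    "allocation": {
        "tolerance": 0.001,
        "coarse_cap": 20000,
        "fine_enabled": True,
        "comp_seed": 1.0,
        "comp_step": 0.001,
        "n_steps": 1,
    },
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return merge_config(cfg or {})


def merge_config(overrides: dict) -> dict:
    """Overlay user settings on the defaults (one level deep)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def shared_legend_classify(
    cover_y1: Raster, cover_y2: Raster, window: int
) -> tuple[Raster, Raster, dict]:
    """Build both land-system maps under one density legend.

    Breakpoints are fitted on the earlier map's dominant fractions (the
    global-legend convention); types that only appear in the later map get
    breaks from that map.
    """
    ty1, fr1 = upscale_dominant_type(cover_y1, window)
    ty2, fr2 = upscale_dominant_type(cover_y2, window)
    breaks = compute_density_breaks(fractions_by_type(ty1, fr1))
    extra = {
        t: f
        for t, f in fractions_by_type(ty2, fr2).items()
        if t not in breaks.breaks and t not in breaks.degenerate
    }
    if extra:
        later = compute_density_breaks(extra)
        breaks.breaks.update(later.breaks)
        breaks.degenerate |= later.degenerate
    ls1 = classify_density(ty1, fr1, breaks)
    ls2 = classify_density(ty2, fr2, breaks)
    return ls1, ls2, breaks.to_dict()


def coarsen_drivers(
    drivers: dict[str, np.ndarray], fine_shape, window: int, coarse_shape
) -> dict[str, np.ndarray]:
    """Block-mean fine driver layers down to the land-system resolution."""
    nr, nc = coarse_shape
    out = {}
    for name, layer in drivers.items():
        block = np.asarray(layer)[: nr * window, : nc * window]
        out[name] = block.reshape(nr, window, nc, window).mean(axis=(1, 3))
    return out


def _jsonable(obj):
    if isinstance(obj, Undefined):
        return {"undefined": obj.reason}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full synthetic-scene pipeline; write artifacts and a report.

    Returns the report dict (also written as report.json). Artifacts:
    cover/land-system rasters, the simulated map, supply-capacity and
    demand CSVs, the change log CSV, and run metadata.
    """
    cfg = merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # -- stage 1: scene and land systems ----------------------------------
    scene_kwargs = dict(cfg["scene"])
    scene_kwargs["shape"] = tuple(scene_kwargs.get("shape", (300, 300)))
    spec = SceneSpec(seed=seed, **scene_kwargs)
    cover_y1 = generate_landscape(spec)
    drivers_fine, driver_truth = generate_drivers(cover_y1, seed=seed + 1)
    rules = [TransitionRule(**r) for r in cfg["rules"]]
    cover_y2, transition_truth = generate_transition_pair(
        cover_y1, rules, seed=seed + 2, drivers=drivers_fine
    )
    window = int(cfg["window"])
    ls_y1, ls_y2, breaks = shared_legend_classify(cover_y1, cover_y2, window)

    # -- stage 2: demand and supply ----------------------------------------
    mask = cover_y2.with_values(np.ones(cover_y2.shape, dtype=np.int8))
    demand_end = demand_from_landcover(cover_y2, mask)
    ca = compute_supply_capacity(cover_y1, ls_y1)
    supply_start = supply_from_grid(ls_y1, ca)

    # -- stage 3: conversion permissions, resistance, suitability ----------
    matrix = derive_conversion_matrix(ls_y1, ls_y2)
    resistance = estimate_resistance(ls_y1, ls_y2)
    drivers_coarse = coarsen_drivers(
        drivers_fine, cover_y1.shape, window, ls_y1.shape
    )
    drivers_coarse.update(compute_density_drivers(ls_y1, cover_y1))
    gained = sorted(
        set(np.unique(ls_y2.values[ls_y2.valid_mask()]))
        & set(np.flatnonzero(matrix.sum(axis=0) > 1))
    )
    suit_cfg = cfg["suitability"]
    suitability = {}
    for j in gained:
        try:
            samples = build_training_samples(
                ls_y1, ls_y2, drivers_coarse, int(j),
                target=suit_cfg["target"], seed=seed + 3,
            )
            model = fit_suitability_model(
                samples,
                n_trees=int(suit_cfg["n_trees"]),
                sample_fraction=float(suit_cfg["sample_fraction"]),
                balanced=bool(suit_cfg["balanced"]),
                seed=seed + 4,
            )
            suitability[int(j)] = predict_suitability(model, drivers_coarse)
        except GridError as exc:
            log.info("skipping suitability for class %s: %s", j, exc)

    # -- stage 4: allocation and validation --------------------------------
    alloc_cfg = dict(cfg["allocation"])
    n_steps = int(alloc_cfg.pop("n_steps", 1))
    config_alloc = AllocationConfig(**alloc_cfg)
    start_demand = {d: float(supply_start[i]) for i, d in enumerate(SERVICES)}
    grid = ls_y1
    all_changes: list[tuple[int, int, int, int, int]] = []
    result = None
    for step_demand in interpolate_demand(start_demand, demand_end, n_steps):
        result = allocate(
            grid, suitability, step_demand, ca, matrix, resistance, config_alloc
        )
        grid = result.grid
        all_changes.extend(result.changes)
    simulated = grid

    report = {
        "demand_km2": demand_end,
        "supply_initial_km2": dict(zip(SERVICES, supply_start)),
        "supply_final_km2": dict(zip(SERVICES, result.supply)),
        "converged": result.converged,
        "infeasible": result.infeasible,
        "iterations": result.iterations,
        "n_changes": len(all_changes),
        "validation_30": validation_report(ls_y1, ls_y2, simulated),
        "validation_10": validation_report(
            merge_density(ls_y1), merge_density(ls_y2), merge_density(simulated)
        ),
    }

    # -- artifacts ----------------------------------------------------------
    write_raster(cover_y1, out / "cover_y1.tif")
    write_raster(cover_y2, out / "cover_y2.tif")
    write_raster(ls_y1, out / "ls_y1.tif")
    write_raster(ls_y2, out / "ls_y2.tif")
    write_raster(simulated, out / "ls_simulated.tif")
    pd.DataFrame(ca, columns=list(SERVICES)).to_csv(out / "ca.csv", index_label="class")
    pd.DataFrame(
        [{"service": d, "demand_km2": demand_end[d]} for d in SERVICES]
    ).to_csv(out / "demand.csv", index=False)
    pd.DataFrame(
        all_changes, columns=["iteration", "cell_row", "cell_col", "from", "to"]
    ).to_csv(out / "changes.csv", index=False)
    metadata = {
        "version": __version__,
        "config": _jsonable(cfg),
        "breaks": breaks,
        "driver_truth": driver_truth,
        "transition_truth": transition_truth,
        "suitability_classes": sorted(suitability),
    }
    (out / "metadata.json").write_text(json.dumps(_jsonable(metadata), indent=2))
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report
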