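"""Synthetic inputs with known structure for every stage of the pipeline.

The generators emulate the statistical shape of the method's real inputs —
multi-class, spatially autocorrelated cover rasters; driver stacks whose
layers are linked to the classes with a stated effect size; before/after
map pairs produced by explicit transition rules; geometric demand
trajectories — while recording the ground truth needed by recovery tests
(class-link effect sizes, realized per-class persistence, converted-cell
counts). Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .demand import SERVICES
from .grids import GridError, Raster

DEFAULT_WEIGHTS = (0.18, 0.22, 0.16, 0.10, 0.06, 0.06, 0.06, 0.05, 0.06, 0.05)


@dataclass
class SceneSpec:
    """Recipe for one synthetic cover raster.

    correlation_length 0 gives i.i.d. multinomial cells; larger values
    smooth a Gaussian field before classing, producing contiguous patches.
    """

    shape: tuple[int, int] = (200, 200)
    n_types: int = 10
    correlation_length: float = 4.0
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    cell_size: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(w) != self.n_types:
            raise GridError("one abundance weight per cover type required")
        if (w < 0).any() or w.sum() == 0:
            raise GridError("weights must be non-negative and not all zero")


def generate_landscape(spec: SceneSpec) -> Raster:
    """Seeded autocorrelated categorical raster with target class shares.

    A smoothed Gaussian field is rank-uniformized and partitioned at the
    cumulative weights, so realized shares track the weights to within
    rounding while contiguous field values yield contiguous patches.
    """
    rng = np.random.default_rng(spec.seed)
    field_ = rng.standard_normal(spec.shape)
    if spec.correlation_length > 0:
        field_ = ndimage.gaussian_filter(field_, spec.correlation_length)
    else:
        # i.i.d. multinomial draw, no spatial structure
        w = np.asarray(spec.weights, float)
        vals = rng.choice(spec.n_types, size=spec.shape, p=w / w.sum())
        return Raster(vals.astype(np.int16), spec.cell_size, nodata=-1)
    ranks = field_.ravel().argsort().argsort() / (field_.size - 1)
    w = np.asarray(spec.weights, float)
    cum = np.cumsum(w / w.sum())
    vals = np.searchsorted(cum, ranks.reshape(spec.shape), side="right")
    vals = np.clip(vals, 0, spec.n_types - 1)
    return Raster(vals.astype(np.int16), spec.cell_size, nodata=-1)


def generate_drivers(
    cover: Raster,
    seed: int = 0,
    n_smooth: int = 3,
    class_links: dict[str, tuple[int, float]] | None = None,
    noise_sd: float = 1.0,
) -> tuple[dict[str, np.ndarray], dict]:
    """Driver stack: smooth fields + class-linked signals + noise.

    ``class_links`` maps a layer name to (cover class, effect size): that
    layer equals effect_size on cells of the class, 0 elsewhere, plus
    N(0, noise_sd) noise. Returns (layers, ground_truth metadata).
    """
    rng = np.random.default_rng(seed)
    shape = cover.shape
    layers: dict[str, np.ndarray] = {}
    truth: dict = {"class_links": {}, "noise_sd": noise_sd}
    for k in range(n_smooth):
        layers[f"smooth_{k}"] = ndimage.gaussian_filter(
            rng.standard_normal(shape), 6.0
        )
    if class_links is None:
        class_links = {"signal_0": (0, 3.0), "signal_1": (1, 3.0)}
    for name, (cls, effect) in class_links.items():
        signal = np.where(cover.values == cls, effect, 0.0)
        layers[name] = signal + rng.standard_normal(shape) * noise_sd
        truth["class_links"][name] = {"class": int(cls), "effect": float(effect)}
    layers["noise"] = rng.standard_normal(shape)
    return layers, truth


@dataclass
class TransitionRule:
    """One sanctioned from->to conversion between the paired maps.

    If ``driver`` names a layer, the eligible cells are ranked by that
    layer descending and the top ``round(prob * n_eligible)`` convert
    (monotone in the driver, deterministic); otherwise each eligible cell
    converts independently with probability ``prob``. ``cap`` bounds the
    number of conversions either way.
    """

    from_class: int
    to_class: int
    prob: float = 1.0
    driver: str | None = None
    cap: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise GridError(f"rule probability {self.prob} outside [0, 1]")


def generate_transition_pair(
    grid_y1: Raster,
    rules: list[TransitionRule],
    seed: int = 0,
    drivers: dict[str, np.ndarray] | None = None,
) -> tuple[Raster, dict]:
    """Apply transition rules to produce a later map plus ground truth.

    The output differs from the input only by rule-sanctioned transitions;
    each cell changes at most once (rules are applied in order against the
    original map). Ground truth records converted counts per rule and the
    realized per-class persistence.
    """
    rng = np.random.default_rng(seed)
    v1 = grid_y1.values
    v2 = v1.copy()
    present = set(np.unique(v1[grid_y1.valid_mask()]).tolist())
    converted = np.zeros(v1.shape, dtype=bool)
    truth: dict = {"rules": []}
    for rule in rules:
        if rule.from_class not in present:
            raise GridError(f"rule references absent class {rule.from_class}")
        eligible = (v1 == rule.from_class) & ~converted & grid_y1.valid_mask()
        idx = np.flatnonzero(eligible.ravel())
        if rule.driver is not None:
            if drivers is None or rule.driver not in drivers:
                raise GridError(f"rule references unknown driver {rule.driver!r}")
            score = np.asarray(drivers[rule.driver]).ravel()[idx]
            take = int(round(rule.prob * len(idx)))
            chosen = idx[np.argsort(-score, kind="stable")[:take]]
        else:
            chosen = idx[rng.random(len(idx)) < rule.prob]
        if rule.cap is not None:
            chosen = chosen[: rule.cap]
        v2.ravel()[chosen] = rule.to_class
        converted.ravel()[chosen] = True
        truth["rules"].append(
            {
                "from": rule.from_class,
                "to": rule.to_class,
                "converted": int(len(chosen)),
            }
        )
    persistence = {}
    for t in sorted(present):
        sel = (v1 == t) & grid_y1.valid_mask()
        persistence[int(t)] = float(np.mean(v2[sel] == v1[sel]))
    truth["persistence"] = persistence
    return grid_y1.with_values(v2), truth


def generate_demand_trajectory(
    base: dict[str, float], growth_rates: dict[str, float], years: list[int]
) -> pd.DataFrame:
    """Geometric demand trajectory, one row per (year, service), km².

    The first listed year carries the base demand; each subsequent year
    multiplies by (1 + rate) per service. Negative resulting demand is an
    error.
    """
    rows = []
    for s, year in enumerate(years):
        for d in SERVICES:
            value = base[d] * (1.0 + growth_rates.get(d, 0.0)) ** s
            if value < 0 or not np.isfinite(value):
                raise GridError(f"demand for {d} in {year} is invalid: {value}")
            rows.append({"year": year, "service": d, "demand_km2": value})
    return pd.DataFrame(rows)
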