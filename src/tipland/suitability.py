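"""Location suitability (P_loc) from driver rasters.

Per land-system class, a random-forest learner is fitted on per-cell driver
vectors labelled by an observed map pair: sample set A holds cells of the
target class at the first date that left it by the second date, sample set B
holds the rest (the literal "loss" target). A conventional gain-oriented
variant labels A as presence of the class at the second date
(``target="presence_at_y2"``). The model's class-A probability over the
whole grid is the suitability surface P_loc in [0, 1].

The ensemble is 200 trees, each grown on a 25% random subsample of rows
drawn without replacement, with sqrt-feature splits; an optional
class-balanced mode downsamples the majority label first. All randomness
flows from one seed.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .grids import GeometryError, GridError, Raster, check_aligned
from .land_system import COVER_NAMES, N_COVER_TYPES

log = logging.getLogger(__name__)


def compute_density_drivers(ls: Raster, cover: Raster) -> dict[str, np.ndarray]:
    """Density-of-cover driver layers: per coarse cell, the area proportion
    of each cover type among its nested fine cells. Values in [0, 1]; the
    proportions over all layers sum to <= 1 (nodata fine cells excluded)."""
    from .demand import _nesting_window  # shared nesting check

    window = _nesting_window(cover, ls)
    nr, nc = ls.shape
    fine = cover.values[: nr * window, : nc * window]
    valid = cover.valid_mask()[: nr * window, : nc * window]
    blocks = fine.reshape(nr, window, nc, window).swapaxes(1, 2)
    bvalid = valid.reshape(nr, window, nc, window).swapaxes(1, 2)
    total = window * window
    layers = {}
    for t in range(N_COVER_TYPES):
        prop = ((blocks == t) & bvalid).sum(axis=(2, 3)) / total
        layers[f"density_{COVER_NAMES[t]}"] = prop.astype(np.float64)
    return layers


def _driver_matrix(
    drivers: dict[str, np.ndarray], feature_names: list[str] | None = None
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Stack named driver layers into (n_cells, n_features); returns the
    matrix, the feature order, and the all-finite row mask."""
    names = feature_names or sorted(drivers)
    missing = [n for n in names if n not in drivers]
    if missing:
        raise KeyError(f"missing driver features: {missing}")
    shapes = {drivers[n].shape for n in names}
    if len(shapes) != 1:
        raise GeometryError(f"driver layers disagree on shape: {shapes}")
    X = np.stack([np.asarray(drivers[n], dtype=np.float64).ravel() for n in names], axis=1)
    finite = np.isfinite(X).all(axis=1)
    return X, names, finite


def build_training_samples(
    ls_y1: Raster,
    ls_y2: Raster,
    drivers: dict[str, np.ndarray],
    class_code: int,
    target: str = "loss",
    max_b_ratio: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Labelled (X, y, feature_names) samples for one land-system class.

    ``target="loss"``: label 1 (set A) = class ``class_code`` at y1 but not
    at y2; everything else is set B. ``target="presence_at_y2"``: label 1 =
    class present at y2. Set B is downsampled to at most ``max_b_ratio``
    times set A (seeded) to bound memory.
    """
    check_aligned(ls_y1, ls_y2)
    X, names, finite = _driver_matrix(drivers)
    if X.shape[0] != ls_y1.values.size:
        raise GeometryError("drivers not co-registered with the land-system grids")
    v1, v2 = ls_y1.values.ravel(), ls_y2.values.ravel()
    valid = finite & ls_y1.valid_mask().ravel() & ls_y2.valid_mask().ravel()
    if not ((v1 == class_code) & valid).any():
        raise GridError(f"class {class_code} absent from the y1 map")
    if target == "loss":
        is_a = (v1 == class_code) & (v2 != class_code)
    elif target == "presence_at_y2":
        is_a = v2 == class_code
    else:
        raise ValueError(f"unknown suitability target {target!r}")
    y = np.where(is_a, 1, 0)[valid]
    X = X[valid]
    idx_a = np.flatnonzero(y == 1)
    idx_b = np.flatnonzero(y == 0)
    cap = int(max_b_ratio * max(len(idx_a), 1))
    if len(idx_b) > cap:
        rng = np.random.default_rng(seed)
        idx_b = rng.choice(idx_b, size=cap, replace=False)
    keep = np.sort(np.concatenate([idx_a, idx_b]))
    return X[keep], y[keep], names


class SuitabilityModel:
    """Random-forest suitability learner with a fit/predict surface.

    Parameters
    ----------
    n_trees : ensemble size (200 by default).
    sample_fraction : per-tree row subsample drawn without replacement (0.25).
    balanced : downsample the majority label to the minority size before
        fitting (seeded) instead of plain row subsampling.
    seed : single seed driving subsampling and tree construction.
    """

    def __init__(
        self,
        n_trees: int = 200,
        sample_fraction: float = 0.25,
        balanced: bool = False,
        seed: int = 0,
    ):
        self.n_trees = n_trees
        self.sample_fraction = sample_fraction
        self.balanced = balanced
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray, feature_names: list[str]):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise GridError(
                "single-label sample set: augment with synthetic counter-"
                "examples or skip this class"
            )
        if self.balanced:
            rng = np.random.default_rng(self.seed)
            idx1, idx0 = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
            n = min(len(idx1), len(idx0))
            keep = np.sort(np.concatenate([
                rng.choice(idx1, n, replace=False),
                rng.choice(idx0, n, replace=False),
            ]))
            X, y = X[keep], y[keep]
        n_rows = max(1, round(self.sample_fraction * len(y)))
        self._forest = BaggingClassifier(
            estimator=DecisionTreeClassifier(max_features="sqrt"),
            n_estimators=self.n_trees,
            max_samples=n_rows,
            bootstrap=False,
            random_state=self.seed,
        )
        self._forest.fit(X, y)
        self.feature_names_ = list(feature_names)
        return self

    def predict_proba_grid(self, drivers: dict[str, np.ndarray]) -> np.ndarray:
        """Class-A probability surface over the driver grid; cells with any
        non-finite driver value become NaN."""
        if not hasattr(self, "feature_names_"):
            raise RuntimeError("model is not fitted")
        X, _, finite = _driver_matrix(drivers, self.feature_names_)
        shape = next(iter(drivers.values())).shape
        out = np.full(X.shape[0], np.nan)
        if finite.any():
            proba = self._forest.predict_proba(X[finite])
            col = list(self._forest.classes_).index(1)
            out[finite] = proba[:, col]
        return out.reshape(shape)


def fit_suitability_model(
    samples: tuple[np.ndarray, np.ndarray, list[str]], **kwargs
) -> SuitabilityModel:
    """Fit the default 200-tree / 25%-subsample forest on labelled samples."""
    X, y, names = samples
    return SuitabilityModel(**kwargs).fit(X, y, names)


def predict_suitability(
    model: SuitabilityModel, drivers: dict[str, np.ndarray]
) -> np.ndarray:
    """Suitability surface P_loc for the model's class over ``drivers``."""
    return model.predict_proba_grid(drivers)
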