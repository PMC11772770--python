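"""Map-agreement and change-prediction accuracy.

Two statistics are computed between an observed and a simulated categorical
map: the chance-corrected overall agreement

    Kappa = (P0 - Pc) / (1 - Pc)

with P0 the observed agreement proportion and Pc the expected agreement of
independent maps with the same marginals (Cohen's convention), and — given
also the initial map — the figure of merit

    FoM = B / (A + B + C + D)

over cells that changed in reality or in the simulation: A changed in
reality only, B changed in both to the same class, C changed in both but to
different classes, D changed in the simulation only. Degenerate inputs
(single-class agreement, no change anywhere) yield a typed Undefined
outcome instead of a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Raster, check_aligned


@dataclass(frozen=True)
class Undefined:
    """Typed outcome for metrics with no defined value on this input."""

    reason: str


@dataclass
class ConfusionTable:
    counts: np.ndarray  # (K, K), observed x simulated
    classes: np.ndarray  # class codes indexing the table

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class ChangeComponents:
    A: int  # changed in reality, not in the simulation
    B: int  # changed in both, to the correct class
    C: int  # changed in both, to the wrong class
    D: int  # changed in the simulation only

    @property
    def total(self) -> int:
        return self.A + self.B + self.C + self.D


def _paired_values(observed: Raster, simulated: Raster) -> tuple[np.ndarray, np.ndarray]:
    check_aligned(observed, simulated)
    valid = observed.valid_mask() & simulated.valid_mask()
    return observed.values[valid], simulated.values[valid]


def confusion(observed: Raster, simulated: Raster) -> ConfusionTable:
    """Cross-tabulate observed vs simulated classes, nodata excluded pairwise."""
    o, s = _paired_values(observed, simulated)
    classes = np.unique(np.concatenate([o, s]))
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    oi = np.searchsorted(classes, o)
    si = np.searchsorted(classes, s)
    np.add.at(counts, (oi, si), 1)
    return ConfusionTable(counts=counts, classes=classes)


def kappa(table: ConfusionTable) -> float | Undefined:
    """Cohen's kappa from a confusion table.

    P0 is the diagonal proportion; Pc the marginal-product chance agreement.
    A table whose chance agreement is 1 (single class on both maps) has no
    defined kappa.
    """
    n = table.n
    if n == 0:
        return Undefined("empty confusion table")
    p0 = np.trace(table.counts) / n
    row = table.counts.sum(axis=1)
    col = table.counts.sum(axis=0)
    pc = float(np.dot(row, col)) / (n * n)
    if pc == 1.0:
        return Undefined("degenerate single-class table (Pc = 1)")
    return float((p0 - pc) / (1.0 - pc))


def change_components(
    initial: Raster, observed: Raster, simulated: Raster
) -> ChangeComponents:
    """Classify every cell into the A/B/C/D change components.

    Cells unchanged in both reality and the simulation belong to none of
    the four components.
    """
    check_aligned(initial, observed, simulated)
    valid = initial.valid_mask() & observed.valid_mask() & simulated.valid_mask()
    init = initial.values[valid]
    obs = observed.values[valid]
    sim = simulated.values[valid]
    real_change = obs != init
    sim_change = sim != init
    return ChangeComponents(
        A=int(np.sum(real_change & ~sim_change)),
        B=int(np.sum(real_change & sim_change & (sim == obs))),
        C=int(np.sum(real_change & sim_change & (sim != obs))),
        D=int(np.sum(~real_change & sim_change)),
    )


def figure_of_merit(comp: ChangeComponents) -> float | Undefined:
    """FoM = B / (A + B + C + D); undefined when no cell changed anywhere."""
    if comp.total == 0:
        return Undefined("no observed or simulated change")
    return comp.B / comp.total


def validation_report(
    initial: Raster, observed: Raster, simulated: Raster
) -> dict:
    """Kappa, FoM and the change components for one map triple."""
    table = confusion(observed, simulated)
    comp = change_components(initial, observed, simulated)
    k = kappa(table)
    fom = figure_of_merit(comp)
    return {
        "kappa": k if isinstance(k, Undefined) else float(k),
        "fom": fom if isinstance(fom, Undefined) else float(fom),
        "components": {"A": comp.A, "B": comp.B, "C": comp.C, "D": comp.D},
        "n_classes": int(len(table.classes)),
        "n_cells": table.n,
    }
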