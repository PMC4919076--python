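"""Population-level utilization distribution: combine per-segment UDs by
fix-count weighting and ordinate cells into use categories.

Categories follow the exposure-strata convention: nonzero cells are ranked
by UD value and binned from highest use (category 20, the top 20%) to
lowest (category 100).  Two ordination modes are offered because "top 20%"
admits two readings: count-quantile (top 20% of *cells*, the default) and
volume-quantile (cells holding the top 20% of UD *mass*).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo_io import Grid, UDRaster

log = logging.getLogger(__name__)

CATEGORY_LEVELS = (20, 40, 60, 80, 100)
BACKGROUND = 0


@dataclass
class CategoryMap:
    """Per-cell UD category: 20/40/60/80/100, or 0 for background cells
    whose UD value falls below the nonzero threshold."""

    grid: Grid
    categories: np.ndarray          # int array, shape (n_rows, n_cols)
    mode: str

    def __post_init__(self):
        if self.categories.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("categories shape must match grid")
        bad = set(np.unique(self.categories)) - set(CATEGORY_LEVELS) - {BACKGROUND}
        if bad:
            raise ValueError(f"invalid category values {bad}")

    def area_table(self) -> pd.DataFrame:
        """Cells and hectares per category (1 km cell = 100 ha)."""
        rows = []
        for cat in CATEGORY_LEVELS:
            n = int((self.categories == cat).sum())
            rows.append({"category": cat, "cells": n,
                         "hectares": n * self.grid.cell_area_ha})
        return pd.DataFrame(rows)


def combine_uds(uds: list[UDRaster]) -> UDRaster:
    """Fix-count-weighted mean of per-segment UDs on a shared grid.

    Population cell value = sum_t w_t U_t / sum_t w_t with w_t the number
    of fixes behind segment t's surface, then renormalized to sum to 1.
    Weighting by fixes (rather than equally per track) relates exposure to
    the time an individual spent on the landscape.
    """
    if not uds:
        raise ValueError("no UDs to combine")
    grid = uds[0].grid
    for ud in uds[1:]:
        if ud.grid != grid:
            raise ValueError("all UDs must share an identical grid")
    weights = np.array([max(ud.n_fixes, 0) for ud in uds], dtype=float)
    if weights.sum() <= 0:
        weights[:] = 1.0
    acc = np.zeros_like(uds[0].values)
    for w, ud in zip(weights, uds):
        acc += w * ud.values
    acc /= weights.sum()
    total_fixes = int(sum(ud.n_fixes for ud in uds))
    return UDRaster(grid, acc / acc.sum(), n_fixes=total_fixes)


def categorize(ud: UDRaster, mode: str = "count-quantile",
               breaks=CATEGORY_LEVELS,
               nonzero_threshold: float | None = None) -> CategoryMap:
    """Ordinate UD cells into disjoint use categories.

    count-quantile: rank nonzero cells by value descending (ties broken by
    row-major cell index); the first 20% of nonzero cells get category 20,
    the next 20% category 40, and so on.

    volume-quantile: walk the same ranking accumulating UD mass; cells up
    to 20% of total mass get category 20, up to 40% category 40, etc.

    Cells below ``nonzero_threshold`` (default 1e-12 x max cell value) are
    background.
    """
    if mode not in ("count-quantile", "volume-quantile"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = ud.values.ravel()
    vmax = vals.max()
    if vmax <= 0:
        warnings.warn("all UD cells are zero; category map is all background")
        return CategoryMap(ud.grid, np.zeros(ud.values.shape, dtype=int), mode)
    thr = 1e-12 * vmax if nonzero_threshold is None else nonzero_threshold
    nz = np.flatnonzero(vals > thr)
    # descending by value, ties by row-major index (stable sort on -value)
    order = nz[np.argsort(-vals[nz], kind="stable")]
    cats = np.zeros(vals.size, dtype=int)
    k = len(breaks)
    if mode == "count-quantile":
        bounds = np.floor(np.arange(1, k + 1) / k * len(order) + 0.5).astype(int)
        start = 0
        for cat, stop in zip(breaks, bounds):
            cats[order[start:stop]] = cat
            start = stop
        cats[order[start:]] = breaks[-1]
    else:
        cum = np.cumsum(vals[order])
        total = cum[-1]
        frac_prev = np.concatenate([[0.0], cum[:-1]]) / total
        # a cell belongs to the first bin whose mass bound its *preceding*
        # cumulative mass has not yet reached (tol for float accumulation)
        for cat, frac in zip(breaks, np.arange(1, k + 1) / k):
            sel = (cats[order] == 0) & (frac_prev < frac - 1e-12)
            cats[order[sel]] = cat
        cats[order[cats[order] == 0]] = breaks[-1]
    cm = CategoryMap(ud.grid, cats.reshape(ud.values.shape), mode)
    log.info("categorize: %d nonzero cells, mode=%s", len(order), mode)
    return cm
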