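"""Flight-hazard overlap: turbines and commercially viable wind-power
classes overlaid on the UD category map.

Produces the per-category report — UD hectares, hectares overlapping wind
power class >= 3 (the classes used for utility-scale wind planning), and
counts of installed turbines of total height >= 100 m AGL — plus the
derived headline percentages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geo_io import TurbineSet, UDRaster
from .population import BACKGROUND, CATEGORY_LEVELS, CategoryMap

log = logging.getLogger(__name__)


def round_half_up(x) -> int:
    """Round half away from zero, the convention for the report's integer
    percentages (e.g. 1185/3123 -> 38)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def count_turbines(category_map: CategoryMap, turbines: TurbineSet,
                   min_height_m: float = 100.0) -> dict:
    """Assign each turbine of height >= min_height_m to the UD category of
    its containing cell (half-open cell convention).

    Returns {category: count} plus 'background', 'out_of_extent', and
    'no_height' (turbines lacking a height attribute, excluded from the
    filter set), and 'total_filtered'.
    """
    h = turbines.height_m
    no_height = np.isnan(h)
    if no_height.any():
        log.info("count_turbines: %d turbines lack height, excluded",
                 int(no_height.sum()))
    keep = ~no_height & (h >= min_height_m)
    x, y = turbines.x[keep], turbines.y[keep]
    grid = category_map.grid
    inside = grid.contains(x, y)
    counts = {cat: 0 for cat in CATEGORY_LEVELS}
    counts["background"] = 0
    ci, cj = grid.cell_index(x[inside], y[inside])
    for cat in np.asarray(category_map.categories)[cj, ci]:
        key = "background" if cat == BACKGROUND else int(cat)
        counts[key] += 1
    counts["out_of_extent"] = int((~inside).sum())
    counts["no_height"] = int(no_height.sum())
    counts["total_filtered"] = int(keep.sum())
    return counts


def wpc_overlap(category_map: CategoryMap, wpc: UDRaster,
                min_class: int = 3) -> dict:
    """Hectares per UD category where wind power class >= min_class.

    The WPC raster is resampled to the category grid by nearest neighbor
    (sampling the WPC cell containing each category-cell center); bilinear
    resampling would invent classes.
    """
    grid = category_map.grid
    if wpc.grid == grid:
        classes = wpc.values
    else:
        if abs(wpc.grid.cell_size - grid.cell_size) > grid.cell_size:
            log.info("wpc_overlap: resampling WPC from %.0f m to %.0f m cells",
                     wpc.grid.cell_size, grid.cell_size)
        xi, yj = np.meshgrid(grid.x_centers(), grid.y_centers())
        ci, cj = wpc.grid.cell_index(xi, yj)
        inside = (ci >= 0) & (ci < wpc.grid.n_cols) \
            & (cj >= 0) & (cj < wpc.grid.n_rows)
        if not inside.any():
            raise ValueError("WPC raster does not overlap the category grid")
        classes = np.full(xi.shape, np.nan)
        classes[inside] = wpc.values[cj[inside], ci[inside]]
    viable = np.nan_to_num(classes, nan=0.0) >= min_class
    out = {}
    for cat in CATEGORY_LEVELS:
        cells = int(((category_map.categories == cat) & viable).sum())
        out[cat] = cells * grid.cell_area_ha
    return out


def build_report(category_areas_ha: dict, turbine_counts: dict,
                 wpc_overlaps_ha: dict, total_turbines: int | None = None,
                 ) -> pd.DataFrame:
    """Assemble the per-category overlap table with derived percentages.

    Columns: category, ud_hectares, wpc_overlap_ha, installed_turbines,
    turbine_pct (of ``total_turbines``, default the filtered total across
    all categories and background), wpc_overlap_pct (of the category's UD
    area).  Percentages are integers, rounded half away from zero.
    """
    if total_turbines is None:
        total_turbines = sum(int(turbine_counts.get(c, 0)) for c in CATEGORY_LEVELS)
        total_turbines += int(turbine_counts.get("background", 0))
        total_turbines += int(turbine_counts.get("out_of_extent", 0))
    rows = []
    for cat in CATEGORY_LEVELS:
        area = float(category_areas_ha.get(cat, 0.0))
        overlap = float(wpc_overlaps_ha.get(cat, 0.0))
        n_turb = int(turbine_counts.get(cat, 0))
        rows.append({
            "category": cat,
            "ud_hectares": area,
            "wpc_overlap_ha": overlap,
            "installed_turbines": n_turb,
            "turbine_pct": round_half_up(100.0 * n_turb / total_turbines)
            if total_turbines else 0,
            "wpc_overlap_pct": round_half_up(100.0 * overlap / area)
            if area > 0 else 0,
        })
    report = pd.DataFrame(rows)
    if (report["wpc_overlap_ha"] > report["ud_hectares"] + 1e-9).any():
        raise ValueError("WPC overlap exceeds category area")
    return report
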