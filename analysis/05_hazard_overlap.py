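#!/usr/bin/env python
"""Overlay flight hazards on the eagle use categories.

Simulates clustered turbine fields along the corridor and a smooth
wind-power-class raster, then reports, per use category: UD hectares,
hectares with wind power class >= 3, and turbines >= 100 m, with the
derived percentages.  Writes turbines.csv, wpc.asc, and
overlap_report.csv under results/analysis/.
"""

from pathlib import Path

import numpy as np

from flyway.geo_io import read_raster, write_points, write_raster
from flyway.pipeline import PipelineConfig, stage_hazards, stage_overlap
from flyway.population import CategoryMap

OUT = Path("results/analysis")
CONFIG = PipelineConfig(seed=42)


def main() -> None:
    pop = read_raster(OUT / "population_ud.asc")
    pop.values = np.nan_to_num(pop.values)
    cat_ras = read_raster(OUT / "categories.asc")
    catmap = CategoryMap(cat_ras.grid,
                         np.nan_to_num(cat_ras.values).astype(int), CONFIG.mode)
    turbines, wpc = stage_hazards(CONFIG, cat_ras.grid, pop)
    write_points(turbines, OUT / "turbines.csv")
    write_raster(wpc, OUT / "wpc.asc")
    report, counts = stage_overlap(catmap, turbines, wpc, CONFIG)
    report.to_csv(OUT / "overlap_report.csv", index=False)
    print(report.to_string(index=False))
    high = report.set_index("category").loc[[20, 40], "installed_turbines"].sum()
    print(f"\n{counts['total_filtered']} turbines >= 100 m; "
          f"{high} ({100 * high / counts['total_filtered']:.0f}%) stand in "
          f"the high-use corridor (categories 20 & 40)")


if __name__ == "__main__":
    main()
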