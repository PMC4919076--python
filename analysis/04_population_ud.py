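#!/usr/bin/env python
"""Build the population utilization distribution and its use categories.

Per-segment UDs (1 km cells) are combined by fix-count weighting and the
nonzero cells ordinated into five use categories (20 = top 20% of cells).
Writes population_ud.asc, categories.asc, and category_areas.csv under
results/analysis/.
"""

from pathlib import Path

from flyway.geo_io import UDRaster, read_tracks, write_raster
from flyway.pipeline import PipelineConfig, stage_segment, stage_ud
from flyway.population import categorize, combine_uds

OUT = Path("results/analysis")
CONFIG = PipelineConfig(seed=42)


def main() -> None:
    tracks = read_tracks(OUT / "telemetry.csv")
    kept, _ = stage_segment(tracks, CONFIG)
    uds, _, grid = stage_ud(tracks, kept, CONFIG)
    pop = combine_uds(uds)
    write_raster(pop, OUT / "population_ud.asc")
    catmap = categorize(pop, mode=CONFIG.mode)
    write_raster(UDRaster(grid, catmap.categories.astype(float)),
                 OUT / "categories.asc")
    areas = catmap.area_table()
    areas.to_csv(OUT / "category_areas.csv", index=False)
    print(f"combined {len(uds)} segment UDs on a "
          f"{grid.n_cols} x {grid.n_rows} grid of 1 km cells")
    print(areas.to_string(index=False))


if __name__ == "__main__":
    main()
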