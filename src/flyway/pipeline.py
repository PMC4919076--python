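"""End-to-end corridor pipeline: simulate -> segment -> dBBMM -> combine ->
categorize -> overlap, with a manifest for reproducibility.

Every stage is a plain function over in-memory objects so the pipeline is
resumable per stage; ``run_all`` wires them together, writes each artifact,
and records a manifest of config, seed, and artifact hashes.  Reruns with
the same config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import dbbmm, geo_io, hazard, population, segmentation, simulate

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters.  The defaults are the transmitter/analysis
    settings the pipeline is designed around: 17-fix window, margin 7,
    18 m location error, 1 km cells, 100 km migration threshold."""

    # estimation / rasterization
    window: int = 17
    margin: int = 7
    loc_error_sd: float = 18.0
    cell_size: float = 1000.0
    substeps: int = 10
    # segmentation
    min_km: float = 100.0
    min_daily_km: float = 20.0
    max_stopover_days: int = 1
    pad_hours: float = 24.0
    # categorization & hazards
    mode: str = "count-quantile"
    min_class: int = 3
    min_height_m: float = 100.0
    # simulation (used when no input files are given)
    seed: int = 0
    n_individuals: int = 3
    migration_speed: float = 60_000.0   # m/day
    corridor_km: float = 360.0
    sigma_m2: float = 0.5
    n_turbine_clusters: int = 8
    turbines_per_cluster: int = 15
    turbine_cluster_sd_m: float = 2000.0
    # inputs (optional; simulation fills in whatever is missing)
    tracks_path: str | None = None
    turbines_path: str | None = None
    wpc_path: str | None = None

    def bridge_params(self) -> dbbmm.BridgeParams:
        return dbbmm.BridgeParams(window=self.window, margin=self.margin,
                                  loc_error_sd=self.loc_error_sd,
                                  cell_size=self.cell_size,
                                  substeps=self.substeps)

    def __post_init__(self):
        self.bridge_params()        # validates window/margin/substeps

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load a flat key-value JSON config; keyword overrides win."""
        with open(path) as fh:
            kv = json.load(fh)
        kv.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kv)


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: PipelineConfig):
    """Simulate tracks, turbines, and a WPC raster for the demo landscape.

    Each individual does a northbound migration along a shared corridor,
    a residency, and a southbound return; per-individual seeds derive from
    the config seed.
    """
    half = cfg.corridor_km * 1000.0
    corridor = ((0.0, -half / 2), (0.0, half / 2))
    mig_days = cfg.corridor_km * 1000.0 / cfg.migration_speed
    phases = (("resident", 3), ("migrating-north", mig_days),
              ("resident", 6), ("migrating-south", mig_days), ("resident", 3))
    tracks = []
    truths = {}
    for k in range(cfg.n_individuals):
        sc = simulate.SimConfig(
            seed=(cfg.seed * 1000 + k) % (2**31), resident_center=(0.0, -half / 2),
            corridor=corridor, migration_speed=cfg.migration_speed,
            phases=phases, sigma_regimes=((1e9, cfg.sigma_m2),),
            loc_error_sd=cfg.loc_error_sd)
        tr, truth = simulate.simulate_track(sc, individual_id=f"eagle-{k:02d}")
        tracks.append(tr)
        truths[tr.individual_id] = truth
    return tracks, truths


def stage_segment(tracks, cfg: PipelineConfig):
    kept_all, excl_all = [], []
    for tr in tracks:
        segs = segmentation.find_migration_segments(
            tr, min_km=cfg.min_km, min_daily_km=cfg.min_daily_km,
            max_stopover_days=cfg.max_stopover_days)
        segs = [segmentation.pad_segment(s, tr, cfg.pad_hours) for s in segs]
        kept, excl = segmentation.apply_exclusion(segs, window=cfg.window)
        kept_all += kept
        excl_all += excl
    log.info("stage_segment: %d kept, %d excluded", len(kept_all), len(excl_all))
    return kept_all, excl_all


def shared_grid(seg_tracks, profiles, params: dbbmm.BridgeParams,
                min_buffer: float = 30_000.0) -> geo_io.Grid:
    """One grid covering every segment (union of per-segment grids)."""
    grids = [dbbmm.grid_for_track(tr, pr, params, min_buffer)
             for tr, pr in zip(seg_tracks, profiles)]
    x0 = min(g.x0 for g in grids)
    y0 = min(g.y0 for g in grids)
    x1 = max(g.x_max for g in grids)
    y1 = max(g.y_max for g in grids)
    s = params.cell_size
    return geo_io.Grid(x0, y0, s, int(round((x1 - x0) / s)),
                       int(round((y1 - y0) / s)))


def stage_ud(tracks, segments, cfg: PipelineConfig):
    """Fit the variance profile and compute the UD for every segment on a
    shared grid.  Returns (uds, profiles, grid)."""
    params = cfg.bridge_params()
    by_id = {tr.individual_id: tr for tr in tracks}
    seg_tracks = [seg.fixes(by_id[seg.track_id]) for seg in segments]
    profiles = [dbbmm.dynamic_variance(tr, params) for tr in seg_tracks]
    grid = shared_grid(seg_tracks, profiles, params)
    uds = [dbbmm.compute_ud(tr, pr, grid, params)
           for tr, pr in zip(seg_tracks, profiles)]
    return uds, profiles, grid


def stage_hazards(cfg: PipelineConfig, grid: geo_io.Grid,
                  pop: geo_io.UDRaster | None = None):
    """Simulate (or load) the turbine field and WPC raster on the grid.

    Simulated turbine clusters are confined to the corridor actually used
    (the bounding box of nonzero population-UD cells, buffered by 2 km),
    emulating ridgeline wind farms along the flyway."""
    if cfg.turbines_path:
        turbines = geo_io.read_points(cfg.turbines_path)
    else:
        extent = (grid.x0, grid.y0, grid.x_max, grid.y_max)
        if pop is not None:
            rows, cols = np.nonzero(pop.values > 1e-12 * pop.values.max())
            s, buf = grid.cell_size, 2_000.0
            extent = (max(extent[0], grid.x0 + cols.min() * s - buf),
                      max(extent[1], grid.y0 + rows.min() * s - buf),
                      min(extent[2], grid.x0 + (cols.max() + 1) * s + buf),
                      min(extent[3], grid.y0 + (rows.max() + 1) * s + buf))
        turbines = simulate.simulate_turbines(
            (cfg.seed * 1000 + 601) % (2**31), cfg.n_turbine_clusters,
            cfg.turbines_per_cluster, cfg.turbine_cluster_sd_m, extent)
    if cfg.wpc_path:
        wpc = geo_io.read_wpc(cfg.wpc_path)
    else:
        wpc = simulate.simulate_wpc_raster((cfg.seed * 1000 + 602) % (2**31),
                                           grid, smoothness=8.0)
    return turbines, wpc


def stage_overlap(catmap, turbines, wpc, cfg: PipelineConfig):
    areas = {int(r.category): r.hectares
             for r in catmap.area_table().itertuples()}
    counts = hazard.count_turbines(catmap, turbines, cfg.min_height_m)
    overlaps = hazard.wpc_overlap(catmap, wpc, cfg.min_class)
    return hazard.build_report(areas, counts, overlaps), counts


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage, write all artifacts under ``outdir``, and return the
    manifest (also written as manifest.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    if cfg.tracks_path:
        tracks = geo_io.read_tracks(cfg.tracks_path)
    else:
        tracks, _ = stage_simulate(cfg)
    geo_io.write_tracks(tracks, outdir / "telemetry.csv")

    kept, excluded = stage_segment(tracks, cfg)
    if not kept:
        raise RuntimeError("pipeline aborted at stage 'segment': "
                           "no migration segments found")
    by_id = {tr.individual_id: tr for tr in tracks}
    segmentation.segment_table(kept, excluded, by_id).to_csv(
        outdir / "segments.csv", index=False)

    uds, profiles, grid = stage_ud(tracks, kept, cfg)
    for k, (ud, pr, seg) in enumerate(zip(uds, profiles, kept)):
        geo_io.write_raster(ud, outdir / f"ud_segment_{k:03d}.asc")
        seg_tr = seg.fixes(by_id[seg.track_id])
        np.savetxt(outdir / f"variance_segment_{k:03d}.csv",
                   np.column_stack([seg_tr.t[:-1], pr.sigma_m2, pr.counts]),
                   delimiter=",", header="t_start,sigma_m2,n_windows",
                   comments="", fmt="%.10g")

    pop = population.combine_uds(uds)
    geo_io.write_raster(pop, outdir / "population_ud.asc")

    catmap = population.categorize(pop, mode=cfg.mode)
    geo_io.write_raster(
        geo_io.UDRaster(grid, catmap.categories.astype(float)),
        outdir / "categories.asc")
    catmap.area_table().to_csv(outdir / "category_areas.csv", index=False)

    turbines, wpc = stage_hazards(cfg, grid, pop)
    geo_io.write_points(turbines, outdir / "turbines.csv")
    geo_io.write_raster(wpc, outdir / "wpc.asc")

    report, counts = stage_overlap(catmap, turbines, wpc, cfg)
    report.to_csv(outdir / "overlap_report.csv", index=False)

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "n_tracks": len(tracks),
        "n_segments_kept": len(kept),
        "n_segments_excluded": len(excluded),
        "turbine_counts": {str(k): v for k, v in counts.items()},
        "files": {p.name: _sha256(p)
                  for p in sorted(outdir.iterdir())
                  if p.name != "manifest.json"},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run_all: finished in %.1f s -> %s", time.time() - t_start, outdir)
    return manifest
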