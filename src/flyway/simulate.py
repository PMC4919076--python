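"""Synthetic telemetry, turbine fields, and wind-power-class rasters.

The generators emulate the study conditions the pipeline is built for:
solar-powered GPS transmitters reporting hourly daylight fixes plus one
midnight fix with ~18 m location error; individuals alternating between
residency (pure Brownian wandering around a home center) and directed
migration (Brownian motion with drift along a corridor polyline); turbine
fields clustered along ridgelines; and a spatially smooth wind-power-class
surface.  Every generator is deterministic under a fixed seed and returns
the ground truth needed for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geo_io import Grid, Track, TurbineSet, UDRaster

SECONDS_PER_DAY = 86400.0


@dataclass
class SimConfig:
    """Configuration for one simulated individual's track.

    ``phases`` is the behavioral schedule: (label, duration_days) with label
    in {"resident", "migrating-north", "migrating-south"}.  ``sigma_regimes``
    is an independent schedule of (duration_hours, sigma_m2) pairs giving the
    Brownian motion variance in m^2/s; the last regime extends to the end of
    the track.
    """

    seed: int = 0
    resident_center: tuple[float, float] = (0.0, 0.0)
    corridor: tuple[tuple[float, float], ...] = ((0.0, 0.0), (0.0, 1.0e6))
    migration_speed: float = 100_000.0      # m/day along the corridor
    phases: tuple[tuple[str, float], ...] = (
        ("resident", 5), ("migrating-north", 10), ("resident", 5))
    sigma_regimes: tuple[tuple[float, float], ...] = ((1e9, 0.5),)
    loc_error_sd: float = 18.0
    day_start_hour: int = 6
    day_end_hour: int = 19
    night_fix: bool = True

    def __post_init__(self):
        if not self.sigma_regimes:
            raise ValueError("sigma_regimes must be nonempty")
        if any(s < 0 for _, s in self.sigma_regimes):
            raise ValueError("sigma_m2 must be >= 0")
        if self.loc_error_sd < 0:
            raise ValueError("loc_error_sd must be >= 0")
        for label, _ in self.phases:
            if label not in ("resident", "migrating-north", "migrating-south"):
                raise ValueError(f"unknown phase label {label!r}")
        if not all(np.isfinite(c) for pt in self.corridor for c in pt):
            raise ValueError("corridor coordinates must be finite")


@dataclass
class SimTruth:
    """Ground truth recorded by simulate_track for recovery tests."""

    true_x: np.ndarray
    true_y: np.ndarray
    #: per-interval time-averaged sigma_m2 (m^2/s), length n_fixes - 1
    interval_sigma_m2: np.ndarray
    #: times (epoch s) at which sigma_m2 changes regime
    change_point_times: np.ndarray
    #: one label per fix: resident | migrating-north | migrating-south
    phase_labels: np.ndarray


def _fix_times(n_days: float, day_start: int, day_end: int, night_fix: bool,
               t0: float = 0.0) -> np.ndarray:
    """Hourly daylight fix schedule plus an optional midnight fix."""
    times = []
    for d in range(int(np.ceil(n_days))):
        base = t0 + d * SECONDS_PER_DAY
        if night_fix:
            times.append(base)          # 00:00
        for h in range(day_start, day_end + 1):
            times.append(base + h * 3600.0)
    times = np.array(times)
    return times[times <= t0 + n_days * SECONDS_PER_DAY]


def _corridor_point(corridor: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    """Point at arc length s along the polyline (clamped to its ends)."""
    s = np.clip(s, 0.0, cum[-1])
    k = np.searchsorted(cum[1:], s, side="right")
    k = min(k, len(corridor) - 2)
    seg_len = cum[k + 1] - cum[k]
    frac = 0.0 if seg_len == 0 else (s - cum[k]) / seg_len
    return corridor[k] + frac * (corridor[k + 1] - corridor[k])


def simulate_track(config: SimConfig, individual_id: str = "sim-1",
                   t0: float = 0.0) -> tuple[Track, SimTruth]:
    """Simulate one individual's observed track and its ground truth.

    The true path is Brownian motion with per-regime variance sigma_m2
    (variance sigma_m2 * dt per coordinate per interval) around a drift:
    zero drift while resident, drift along the corridor at migration_speed
    while migrating (southbound reverses the polyline direction).  Observed
    position = true position + isotropic Gaussian error with SD
    loc_error_sd.
    """
    rng = np.random.default_rng(config.seed)
    total_days = sum(d for _, d in config.phases)
    t = _fix_times(total_days, config.day_start_hour, config.day_end_hour,
                   config.night_fix, t0)
    n = len(t)
    if n < 2:
        raise ValueError("simulation too short: fewer than 2 fixes")

    # phase label per fix
    bounds = t0 + np.cumsum([0.0] + [d * SECONDS_PER_DAY for _, d in config.phases])
    labels = np.empty(n, dtype=object)
    for (label, _), lo, hi in zip(config.phases, bounds[:-1], bounds[1:]):
        labels[(t >= lo) & (t < hi)] = label
    labels[t >= bounds[-1]] = config.phases[-1][0]

    # sigma regime boundaries (epoch s); last regime extends indefinitely
    reg_t = t0 + np.cumsum([0.0] + [dur * 3600.0 for dur, _ in config.sigma_regimes])
    reg_sigma = np.array([s for _, s in config.sigma_regimes])

    def integrated_sigma(ta: float, tb: float) -> float:
        """Integral of sigma_m2 over [ta, tb] (handles regime changes)."""
        total = 0.0
        for k, s in enumerate(reg_sigma):
            lo = reg_t[k]
            hi = reg_t[k + 1] if k + 1 < len(reg_t) else np.inf
            if k == len(reg_sigma) - 1:
                hi = np.inf
            ov = max(0.0, min(tb, hi) - max(ta, lo))
            total += s * ov
        return total

    corridor = np.asarray(config.corridor, float)
    seg = np.diff(corridor, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    true = np.empty((n, 2))
    true[0] = config.resident_center
    # arc-length progress along the corridor, anchored at the point nearest
    # the start position's projection (start of polyline by default)
    s_pos = 0.0
    interval_sigma = np.empty(n - 1)
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        var = integrated_sigma(t[i], t[i + 1])
        interval_sigma[i] = var / dt
        drift = np.zeros(2)
        label = labels[i]
        if label != "resident":
            step = config.migration_speed * dt / SECONDS_PER_DAY
            if label == "migrating-north":
                p0 = _corridor_point(corridor, cum, s_pos)
                p1 = _corridor_point(corridor, cum, s_pos + step)
                s_pos += step
            else:
                p0 = _corridor_point(corridor, cum, s_pos)
                p1 = _corridor_point(corridor, cum, s_pos - step)
                s_pos -= step
            drift = p1 - p0
        true[i + 1] = true[i] + drift + rng.normal(0.0, np.sqrt(var), size=2)

    obs = true + rng.normal(0.0, config.loc_error_sd, size=(n, 2))
    track = Track(individual_id, t, obs[:, 0], obs[:, 1],
                  np.full(n, config.loc_error_sd))
    cps = reg_t[1:len(reg_sigma)]
    truth = SimTruth(true[:, 0].copy(), true[:, 1].copy(), interval_sigma,
                     np.asarray(cps, float), labels)
    return track, truth


def simulate_turbines(seed: int, n_clusters: int, turbines_per_cluster: int,
                      cluster_sd_m: float,
                      extent: tuple[float, float, float, float],
                      height_range_m: tuple[float, float] = (80.0, 160.0),
                      ) -> TurbineSet:
    """Poisson-cluster turbine field inside ``extent`` (x0, y0, x1, y1).

    Cluster centers are uniform in the extent; turbines scatter around their
    center with isotropic SD ``cluster_sd_m`` (resampled until inside the
    extent, emulating ridgeline wind farms that stay within the mapped
    area).  Heights are uniform in ``height_range_m``.
    """
    x0, y0, x1, y1 = extent
    if not (x1 > x0 and y1 > y0):
        raise ValueError("degenerate extent")
    rng = np.random.default_rng(seed)
    centers = np.column_stack([rng.uniform(x0, x1, n_clusters),
                               rng.uniform(y0, y1, n_clusters)])
    xs, ys = [], []
    for cx, cy in centers:
        placed = 0
        while placed < turbines_per_cluster:
            px, py = rng.normal((cx, cy), cluster_sd_m)
            if x0 <= px < x1 and y0 <= py < y1:
                xs.append(px)
                ys.append(py)
                placed += 1
    n = len(xs)
    heights = rng.uniform(height_range_m[0], height_range_m[1], n)
    return TurbineSet(np.array(xs), np.array(ys), heights)


def simulate_wpc_raster(seed: int, grid: Grid, smoothness: float = 5.0,
                        class_probs=None) -> UDRaster:
    """Smooth integer wind-power-class raster (classes 1-7) on ``grid``.

    A Gaussian-filtered white-noise latent field is thresholded at its own
    empirical quantiles so marginal class frequencies match ``class_probs``
    (default: mass concentrated on low classes, as for onshore wind maps).
    ``smoothness`` is the filter SD in cells.
    """
    if class_probs is None:
        class_probs = np.array([0.35, 0.25, 0.15, 0.10, 0.07, 0.05, 0.03])
    class_probs = np.asarray(class_probs, float)
    if class_probs.shape != (7,):
        raise ValueError("class_probs must have 7 entries")
    if abs(class_probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_probs must sum to 1")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal((grid.n_rows, grid.n_cols))
    if smoothness > 0:
        latent = ndimage.gaussian_filter(latent, smoothness, mode="reflect")
    # rank-based thresholding: exact class frequencies up to rounding
    flat = latent.ravel()
    order = np.argsort(flat, kind="stable")
    n = flat.size
    counts = np.floor(np.cumsum(class_probs) * n + 0.5).astype(int)
    classes = np.empty(n, dtype=float)
    start = 0
    for c, stop in enumerate(counts, start=1):
        classes[order[start:stop]] = c
        start = stop
    classes[order[counts[-1]:]] = 7
    return UDRaster(grid, classes.reshape(grid.n_rows, grid.n_cols))
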