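"""Dynamic Brownian bridge movement model (dBBMM).

Consecutive GPS fixes are joined by Brownian bridges whose motion variance
sigma_m2 (m^2/s) may change along the track.  sigma_m2 is estimated by a
leave-one-out likelihood: alternating fixes are treated as observations of
the bridge spanned by their neighbors.  A sliding window compares, by BIC,
a single-variance model against one-breakpoint models, producing a
per-interval variance profile; the utilization distribution is then the
time integral of the bridge density rasterized onto the analysis grid.

The default parameters (window 17, margin 7, 18 m location error, 1 km
cells) match a transmitter duty cycle of at most 17 fixes per day.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .geo_io import Grid, Track, UDRaster

log = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class BridgeParams:
    """Estimation and rasterization parameters.

    window: sliding-window length in fixes (odd, >= 2*margin + 3).
    margin: minimum fixes each sub-segment must contain for a breakpoint.
    loc_error_sd: fallback GPS error SD (m) when a fix carries none.
    cell_size: raster cell size (m).
    substeps: bridge-density evaluations per fix interval (midpoint rule).
    sigma_search: (lo, hi, n) log-spaced search grid for sigma_m2 in m^2/s.
    allow_breakpoints: disable to force the static single-variance model.
    """

    window: int = 17
    margin: int = 7
    loc_error_sd: float = 18.0
    cell_size: float = 1000.0
    substeps: int = 10
    sigma_search: tuple[float, float, int] = (1e-4, 1e4, 200)
    allow_breakpoints: bool = True

    def __post_init__(self):
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.margin < 3:
            raise ValueError("margin must be >= 3")
        if self.allow_breakpoints and self.window < 2 * self.margin + 3:
            raise ValueError("window must be >= 2*margin + 3")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")


@dataclass
class VarianceProfile:
    """Per-interval motion variance along a segment.

    sigma_m2[i] applies to the bridge between fixes i and i+1; counts[i]
    is the number of sliding windows whose model informed that interval.
    """

    sigma_m2: np.ndarray
    counts: np.ndarray
    n_windows: int = 0
    n_breakpoint_windows: int = 0

    def __post_init__(self):
        if np.any(self.sigma_m2 < 0):
            raise ValueError("sigma_m2 must be >= 0")


def bridge_moments(z_i, z_j, t_i: float, t_j: float, t, sigma_m2: float,
                   err_i: float = 0.0, err_j: float = 0.0):
    """Mean and per-coordinate variance of the Brownian bridge at time t.

    With alpha = (t - t_i)/(t_j - t_i) and T = t_j - t_i:
      mean     = (1 - alpha) z_i + alpha z_j
      variance = T alpha (1 - alpha) sigma_m2
                 + (1 - alpha)^2 err_i^2 + alpha^2 err_j^2
    (isotropic; the same variance applies to both coordinates).
    """
    if sigma_m2 < 0:
        raise ValueError("sigma_m2 must be >= 0")
    t = np.asarray(t, dtype=float)
    if np.any(t <= t_i) or np.any(t > t_j):
        raise ValueError("t must lie in (t_i, t_j]")
    T = t_j - t_i
    alpha = (t - t_i) / T
    z_i = np.asarray(z_i, float)
    z_j = np.asarray(z_j, float)
    mean = np.outer(1.0 - alpha, z_i) + np.outer(alpha, z_j) \
        if t.ndim else (1.0 - alpha) * z_i + alpha * z_j
    var = T * alpha * (1.0 - alpha) * sigma_m2 \
        + (1.0 - alpha) ** 2 * err_i ** 2 + alpha ** 2 * err_j ** 2
    return mean, var


def _loo_stats(t: np.ndarray, x: np.ndarray, y: np.ndarray, err: np.ndarray):
    """Per-left-out-fix constants for the leave-one-out likelihood.

    Left-out fixes are the alternating interior fixes (0-based odd indices
    with both neighbors present).  Returns (a, c, r2) such that the bridge
    variance at left-out fix j is a*sigma_m2 + c and r2 is the squared
    distance from the observed fix to the bridge mean.
    """
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 fixes")
    j = np.arange(1, n - 1, 2)
    T = t[j + 1] - t[j - 1]
    alpha = (t[j] - t[j - 1]) / T
    a = T * alpha * (1.0 - alpha)
    # left-out fix is itself an observation with error: add err[j]^2
    c = (1.0 - alpha) ** 2 * err[j - 1] ** 2 + alpha ** 2 * err[j + 1] ** 2 \
        + err[j] ** 2
    mx = (1.0 - alpha) * x[j - 1] + alpha * x[j + 1]
    my = (1.0 - alpha) * y[j - 1] + alpha * y[j + 1]
    r2 = (x[j] - mx) ** 2 + (y[j] - my) ** 2
    return a, c, r2


def _nll_from_stats(a, c, r2, sigma_m2):
    """Sum of -log circular-bivariate-normal densities; vectorized over a
    1-D array of sigma_m2 values (returns array) or a scalar."""
    sig = np.asarray(sigma_m2, dtype=float)
    s = a[..., None] * sig + c[..., None] if sig.ndim else a * sig + c
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.log(_TWO_PI * s) + r2[..., None] / (2.0 * s) if sig.ndim \
            else np.log(_TWO_PI * s) + r2 / (2.0 * s)
    return np.nansum(terms, axis=0) if sig.ndim else float(np.sum(terms))


def loo_neg_log_likelihood(track: Track, sigma_m2: float) -> float:
    """Leave-one-out negative log likelihood of sigma_m2 for a window slice."""
    a, c, r2 = _loo_stats(track.t, track.x, track.y, track.err_sd)
    return _nll_from_stats(a, c, r2, sigma_m2)


def _fit_sigma_arrays(t, x, y, err, params: BridgeParams):
    """Grid search + parabolic refinement.  Returns (sigma_hat, nll_hat)."""
    a, c, r2 = _loo_stats(t, x, y, err)
    if np.all(r2 == 0) and np.all(c == 0):
        warnings.warn("all positions identical with zero location error; "
                      "returning sigma_m2 = 0", stacklevel=2)
        return 0.0, 0.0
    lo, hi, n = params.sigma_search
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n))
    nll = _nll_from_stats(a, c, r2, grid)
    m = int(np.argmin(nll))
    sig, val = grid[m], nll[m]
    if 0 < m < n - 1:
        # refine within the bracketing grid interval (log-sigma space)
        res = optimize.minimize_scalar(
            lambda l: _nll_from_stats(a, c, r2, float(np.exp(l))),
            bounds=(np.log(grid[m - 1]), np.log(grid[m + 1])),
            method="bounded", options={"xatol": 1e-10})
        if res.fun <= val:
            sig, val = float(np.exp(res.x)), float(res.fun)
    return float(sig), float(val)


def fit_sigma(track: Track, params: BridgeParams = BridgeParams()) -> float:
    """Maximum-likelihood sigma_m2 (m^2/s) for one window slice."""
    sig, _ = _fit_sigma_arrays(track.t, track.x, track.y, track.err_sd, params)
    return sig


def dynamic_variance(track: Track, params: BridgeParams = BridgeParams()
                     ) -> VarianceProfile:
    """Sliding-window BIC change-point estimation of the variance profile.

    Each window of ``params.window`` fixes is fitted with (a) a single
    sigma_m2 and (b) one-breakpoint models with the break at any fix outside
    the ``params.margin`` fixes at either window edge (so each sub-segment,
    sharing the breakpoint fix, keeps at least margin + 1 fixes).
    BIC = 2*NLL + k*ln(n_loo) selects the model;
    the winner assigns its sigma values to the window's non-margin
    intervals.  Each interval's profile value is the mean over all windows
    that assigned to it; intervals never assigned inherit the nearest
    assigned value.
    """
    n = len(track)
    w, m = params.window, params.margin
    if n < w:
        raise ValueError(f"track has {n} fixes < window {w} "
                         "(should have been excluded upstream)")
    t, x, y, err = track.t, track.x, track.y, track.err_sd
    sums = np.zeros(n - 1)
    counts = np.zeros(n - 1, dtype=int)
    n_bp = 0
    n_win = n - w + 1
    # number of left-out fixes in a full window (BIC sample size)
    n_loo = len(np.arange(1, w - 1, 2))
    log_nloo = np.log(n_loo)
    lo_i, hi_i = m, w - 2 - m          # local non-margin interval range
    for w0 in range(n_win):
        sl = slice(w0, w0 + w)
        sig1, nll1 = _fit_sigma_arrays(t[sl], x[sl], y[sl], err[sl], params)
        best_bic = 2.0 * nll1 + log_nloo
        best_b = -1
        best_pair = (sig1, sig1)
        if params.allow_breakpoints:
            # Candidate breakpoints: both sub-segments (sharing the break
            # fix) keep >= margin fixes, and only even local offsets are
            # tested -- the break fix is then a kept (not left-out) fix, so
            # the union of the two sides' leave-one-out sets equals the full
            # window's and the models are compared on identical observations.
            # The break model spends three parameters (two variances plus
            # the estimated break location).
            b_lo = m - 1 + ((m - 1) % 2)
            for b in range(b_lo, w - m + 1, 2):
                sL = slice(w0, w0 + b + 1)
                sR = slice(w0 + b, w0 + w)
                sigL, nllL = _fit_sigma_arrays(t[sL], x[sL], y[sL], err[sL], params)
                sigR, nllR = _fit_sigma_arrays(t[sR], x[sR], y[sR], err[sR], params)
                bic = 2.0 * (nllL + nllR) + 3.0 * log_nloo
                if bic < best_bic:
                    best_bic, best_b, best_pair = bic, b, (sigL, sigR)
        if best_b >= 0:
            n_bp += 1
        if hi_i >= lo_i:
            for i in range(lo_i, hi_i + 1):
                sig = best_pair[0] if (best_b < 0 or i < best_b) else best_pair[1]
                sums[w0 + i] += sig
                counts[w0 + i] += 1
    assigned = counts > 0
    profile = np.zeros(n - 1)
    profile[assigned] = sums[assigned] / counts[assigned]
    if not assigned.any():
        # degenerate: window spans whole short track with huge margin
        sig1, _ = _fit_sigma_arrays(t, x, y, err, params)
        profile[:] = sig1
    elif not assigned.all():
        idx = np.arange(n - 1)
        known = idx[assigned]
        nearest = known[np.argmin(np.abs(idx[:, None] - known[None, :]), axis=1)]
        profile[~assigned] = profile[nearest[~assigned]]
    return VarianceProfile(profile, counts, n_win, n_bp)


def locate_change_point(profile: VarianceProfile, floor: float = 1e-12) -> int:
    """Fix index of the largest variance jump in the profile.

    Jumps are measured on the log scale (the ratio of adjacent interval
    variances), the natural scale for a positive diffusion parameter: an
    absolute jump would be dominated by sampling noise in high-variance
    regimes.  Returns the index of the fix at the jump (the first fix of
    the higher/lower regime boundary).
    """
    lp = np.log(np.maximum(profile.sigma_m2, floor))
    return int(np.argmax(np.abs(np.diff(lp)))) + 1


def grid_for_track(track: Track, profile: VarianceProfile,
                   params: BridgeParams = BridgeParams(),
                   min_buffer: float = 30_000.0) -> Grid:
    """Analysis grid covering the track's bounding box buffered by
    max(min_buffer, 3 * max bridge SD), snapped to cell boundaries."""
    dt = np.diff(track.t)
    err2 = np.maximum(track.err_sd[:-1], track.err_sd[1:]) ** 2
    max_var = float(np.max(0.25 * dt * profile.sigma_m2 + err2))
    buffer = max(min_buffer, 3.0 * np.sqrt(max_var)) + params.cell_size
    s = params.cell_size
    x0 = np.floor((track.x.min() - buffer) / s) * s
    y0 = np.floor((track.y.min() - buffer) / s) * s
    n_cols = int(np.ceil((track.x.max() + buffer - x0) / s))
    n_rows = int(np.ceil((track.y.max() + buffer - y0) / s))
    return Grid(x0, y0, s, n_cols, n_rows)


def compute_ud(track: Track, profile: VarianceProfile, grid: Grid,
               params: BridgeParams = BridgeParams()) -> UDRaster:
    """Integrate the bridge density over time onto the grid.

    Each fix interval contributes ``substeps`` midpoint-rule evaluations of
    the circular normal bridge density, each weighted by dt/substeps.  The
    per-cell mass of each evaluation is integrated exactly (the separable
    Gaussian CDF differenced at cell edges), so the only discretization is
    temporal; the surface is then normalized to sum to 1.
    """
    n = len(track)
    if len(profile.sigma_m2) != n - 1:
        raise ValueError("profile length must be n_fixes - 1")
    t, x, y, err = track.t, track.x, track.y, track.err_sd
    x_edges = grid.x0 + np.arange(grid.n_cols + 1) * grid.cell_size
    y_edges = grid.y0 + np.arange(grid.n_rows + 1) * grid.cell_size
    acc = np.zeros((grid.n_rows, grid.n_cols))
    sub = params.substeps
    alphas = (np.arange(sub) + 0.5) / sub
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        wgt = dt / sub
        sig = profile.sigma_m2[i]
        for alpha in alphas:
            mx = (1.0 - alpha) * x[i] + alpha * x[i + 1]
            my = (1.0 - alpha) * y[i] + alpha * y[i + 1]
            svar = dt * alpha * (1.0 - alpha) * sig \
                + (1.0 - alpha) ** 2 * err[i] ** 2 + alpha ** 2 * err[i + 1] ** 2
            sd = np.sqrt(svar)
            if (mx - 3 * sd < grid.x0 or mx + 3 * sd > grid.x_max
                    or my - 3 * sd < grid.y0 or my + 3 * sd > grid.y_max):
                raise ValueError(
                    "grid does not contain the 3-SD envelope of a bridge; "
                    "enlarge the grid extent (see grid_for_track)")
            if svar == 0.0:
                ci, cj = grid.cell_index(mx, my)
                acc[cj, ci] += wgt
                continue
            denom = sd * np.sqrt(2.0)
            px = np.diff(special.erf((x_edges - mx) / denom))
            py = np.diff(special.erf((y_edges - my) / denom))
            acc += (wgt * 0.25) * np.outer(py, px)
    total = acc.sum()
    if total <= 0:
        raise ValueError("UD accumulated zero mass")
    return UDRaster(grid, acc / total, n_fixes=n)
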