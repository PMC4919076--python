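"""Shared fixtures: deterministic synthetic tracks with known parameters."""

import numpy as np
import pytest

from flyway.geo_io import Track


def make_brownian_track(seed: int, n: int = 200, sigma_m2: float = 0.5,
                        err_sd: float = 0.0, dt: float = 3600.0) -> Track:
    """Pure Brownian track: hourly fixes, known diffusion, optional GPS noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    steps = rng.normal(0.0, np.sqrt(sigma_m2 * dt), (n - 1, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    x = xy[:, 0] + rng.normal(0.0, err_sd, n)
    y = xy[:, 1] + rng.normal(0.0, err_sd, n)
    return Track("brownian", t, x, y, err_sd)


def make_two_regime_track(seed: int, n: int = 300, sigma_lo: float = 0.2,
                          sigma_hi: float = 5.0, cp_fix: int = 150,
                          dt: float = 3600.0) -> Track:
    """Brownian track whose diffusion jumps sigma_lo -> sigma_hi at fix cp_fix.

    Interval i (between fixes i and i+1) uses sigma_lo for i < cp_fix - 1,
    sigma_hi from the interval starting at fix cp_fix - 1, so the first fix
    of the high-variance regime is cp_fix - 1 ... cp_fix boundary; the
    change-point fix index is cp_fix - 1 + 1 = cp_fix in interval terms.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    sig = np.where(np.arange(n - 1) < cp_fix - 1, sigma_lo, sigma_hi)
    steps = rng.normal(0.0, 1.0, (n - 1, 2)) * np.sqrt(sig * dt)[:, None]
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Track("two-regime", t, xy[:, 0], xy[:, 1], 0.0)


@pytest.fixture
def brownian_track() -> Track:
    return make_brownian_track(seed=7)


@pytest.fixture
def three_fix_track() -> Track:
    """The closed-form case: out-and-back triangle with zero GPS error.

    Midpoint 60 m off the chord at half the 3600 s span; the 1-observation
    leave-one-out likelihood is minimized at sigma_m2 = r^2 / (2 T a(1-a))
    = 60^2 / 1800 = 2.0 m^2/s.
    """
    return Track("toy", [0.0, 1800.0, 3600.0], [0.0, 60.0, 0.0],
                 [0.0, 0.0, 0.0], 0.0)
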