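"""Migration-segment extraction: find continuous directional north/south
movements of at least 100 km net displacement, pad them by ~24 h of
neighboring fixes, and exclude segments too short for the sliding-window
variance estimator.

"Continuous directional" is operationalized at the day level: a run of
consecutive days whose daily net north-south displacement exceeds
``min_daily_km`` with a consistent sign, tolerating up to
``max_stopover_days`` consecutive interior days below the threshold.  A run
is accepted as a migration segment when its total net N-S displacement is
at least ``min_km``.  Repeated migrations in one season yield separate
segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geo_io import Track

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MigrationSegment:
    """A directional migratory subset of a parent track.

    ``i0``/``i1`` bound the core fix range (half-open indices into the
    parent track); ``p0``/``p1`` bound the padded range (>= core range).
    """

    track_id: str
    i0: int
    i1: int
    direction: str                 # "north" | "south"
    net_ns_km: float
    p0: int = -1
    p1: int = -1

    def __post_init__(self):
        if self.direction not in ("north", "south"):
            raise ValueError(f"direction must be north|south, got {self.direction!r}")

    @property
    def padded_range(self) -> tuple[int, int]:
        if self.p0 < 0:
            return (self.i0, self.i1)
        return (self.p0, self.p1)

    def n_fixes(self) -> int:
        p0, p1 = self.padded_range
        return p1 - p0

    def fixes(self, track: Track) -> Track:
        p0, p1 = self.padded_range
        return track.slice(p0, p1)


def find_migration_segments(track: Track, min_km: float = 100.0,
                            min_daily_km: float = 20.0,
                            max_stopover_days: int = 1,
                            ) -> list[MigrationSegment]:
    """Find maximal directional day-runs with |net N-S displacement| >= min_km.

    Daily displacement is the difference between the last northing of one
    calendar day (UTC) and the last northing of the previous observed day.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    days = pd.to_datetime(track.t, unit="s", utc=True).normalize()
    day_codes, day_index = pd.factorize(days, sort=True)
    n_days = len(day_index)
    if n_days < 2:
        return []

    # first and last fix index of each observed day
    first_fix = np.full(n_days, -1, dtype=int)
    last_fix = np.full(n_days, -1, dtype=int)
    for i, d in enumerate(day_codes):
        if first_fix[d] < 0:
            first_fix[d] = i
        last_fix[d] = i

    day_y = track.y[last_fix]
    disp_km = np.diff(day_y) / 1000.0           # transition d -> d+1
    sign = np.where(disp_km >= min_daily_km, 1,
                    np.where(disp_km <= -min_daily_km, -1, 0))

    runs: list[tuple[int, int, int]] = []       # (sign, start_day, end_day)
    cur_sign = 0
    start = last_good = -1
    stopover = 0
    for k in range(len(sign)):
        s = sign[k]
        if cur_sign == 0:
            if s != 0:
                cur_sign, start, last_good, stopover = s, k, k + 1, 0
        elif s == cur_sign:
            last_good, stopover = k + 1, 0
        elif s == 0 and stopover < max_stopover_days:
            stopover += 1
        else:
            runs.append((cur_sign, start, last_good))
            cur_sign = s if s != 0 else 0
            if cur_sign:
                start, last_good, stopover = k, k + 1, 0
    if cur_sign != 0:
        runs.append((cur_sign, start, last_good))

    segments = []
    for s, d0, d1 in runs:
        i0 = first_fix[d0]
        i1 = last_fix[d1] + 1
        net_km = (track.y[i1 - 1] - track.y[i0]) / 1000.0
        if abs(net_km) >= min_km and np.sign(net_km) == s:
            segments.append(MigrationSegment(
                track.individual_id, int(i0), int(i1),
                "north" if s > 0 else "south", float(net_km)))
    log.info("find_migration_segments: %s -> %d segments",
             track.individual_id, len(segments))
    return segments


def pad_segment(segment: MigrationSegment, track: Track,
                pad_hours: float = 24.0) -> MigrationSegment:
    """Extend the core range with all fixes within ``pad_hours`` before the
    first and after the last core fix, clipped to the track bounds."""
    pad_s = pad_hours * 3600.0
    t_start = track.t[segment.i0]
    t_end = track.t[segment.i1 - 1]
    p0 = int(np.searchsorted(track.t, t_start - pad_s, side="left"))
    p1 = int(np.searchsorted(track.t, t_end + pad_s, side="right"))
    return replace(segment, p0=p0, p1=p1)


def apply_exclusion(segments: list[MigrationSegment], window: int = 17,
                    ) -> tuple[list[MigrationSegment], list[MigrationSegment]]:
    """Partition segments into (kept, excluded) by the minimum-length rule:
    a segment whose padded fix count is below the sliding-window size cannot
    be modeled and is excluded (reason logged)."""
    kept, excluded = [], []
    for seg in segments:
        if seg.n_fixes() < window:
            log.info("apply_exclusion: %s [%d:%d) excluded (%d fixes < window %d)",
                     seg.track_id, *seg.padded_range, seg.n_fixes(), window)
            excluded.append(seg)
        else:
            kept.append(seg)
    return kept, excluded


def segment_table(segments: list[MigrationSegment],
                  excluded: list[MigrationSegment],
                  tracks: dict[str, Track]) -> pd.DataFrame:
    """Tabulate segments: id, direction, start/end timestamps, net km,
    n_fixes, excluded flag."""
    rows = []
    for seg, is_excl in [(s, False) for s in segments] + [(s, True) for s in excluded]:
        tr = tracks[seg.track_id]
        p0, p1 = seg.padded_range
        rows.append({
            "track_id": seg.track_id,
            "direction": seg.direction,
            "start": pd.Timestamp(tr.t[p0], unit="s", tz="UTC").isoformat(),
            "end": pd.Timestamp(tr.t[p1 - 1], unit="s", tz="UTC").isoformat(),
            "net_ns_km": round(seg.net_ns_km, 3),
            "n_fixes": seg.n_fixes(),
            "excluded": is_excl,
            "reason": f"n_fixes < window" if is_excl else "",
        })
    return pd.DataFrame(rows)
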