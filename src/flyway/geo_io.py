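"""Core spatial containers and file I/O for the corridor pipeline.

Everything downstream operates in a single planar, equal-area CRS in
meters.  Geographic-to-planar conversion is an ingest concern and is not
handled here; synthetic data is generated directly in planar meters.

Formats: Movebank-style telemetry CSV, ESRI ASCII / GeoTIFF rasters,
GeoJSON or CSV turbine points.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: default GPS location-error SD in meters (transmitter manufacturer spec)
DEFAULT_LOC_ERROR_SD = 18.0

TRACK_COLUMNS = ["individual-local-identifier", "timestamp", "x", "y", "loc-error-sd"]


@dataclass(frozen=True)
class Fix:
    """One GPS observation: time (epoch seconds, UTC), planar position (m),
    and the location-error SD (m)."""

    individual_id: str
    t: float
    x: float
    y: float
    err_sd: float = DEFAULT_LOC_ERROR_SD

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y) and np.isfinite(self.t)):
            raise ValueError("Fix coordinates/time must be finite")
        if self.err_sd < 0:
            raise ValueError("err_sd must be >= 0")


class Track:
    """Time-ordered fixes for a single individual.

    Stored as parallel numpy arrays for fast slicing; timestamps are epoch
    seconds (UTC) and must be strictly increasing.
    """

    def __init__(self, individual_id: str, t, x, y, err_sd=None):
        self.individual_id = str(individual_id)
        self.t = np.asarray(t, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if err_sd is None:
            err_sd = np.full_like(self.t, DEFAULT_LOC_ERROR_SD)
        elif np.isscalar(err_sd):
            err_sd = np.full_like(self.t, float(err_sd))
        self.err_sd = np.asarray(err_sd, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.err_sd)):
            raise ValueError("Track arrays must have equal length")
        if len(self.t) and not np.all(np.diff(self.t) > 0):
            raise ValueError("Track timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("Track coordinates must be finite")
        if np.any(self.err_sd < 0):
            raise ValueError("err_sd must be >= 0")

    def __len__(self) -> int:
        return len(self.t)

    def slice(self, i0: int, i1: int) -> "Track":
        """Contiguous sub-track covering fix indices [i0, i1)."""
        return Track(self.individual_id, self.t[i0:i1], self.x[i0:i1],
                     self.y[i0:i1], self.err_sd[i0:i1])

    def to_dataframe(self) -> pd.DataFrame:
        ts = pd.to_datetime(self.t, unit="s", utc=True)
        return pd.DataFrame({
            "individual-local-identifier": self.individual_id,
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "x": self.x,
            "y": self.y,
            "loc-error-sd": self.err_sd,
        })


@dataclass(frozen=True)
class Grid:
    """Regular analysis grid: lower-left origin, square cells of
    ``cell_size`` meters, 0-based (col, row) indexing.

    Cell (i, j) covers the half-open square
    [x0 + i*s, x0 + (i+1)*s) x [y0 + j*s, y0 + (j+1)*s), so a point on a
    shared edge belongs to exactly one cell.
    """

    x0: float
    y0: float
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def x_max(self) -> float:
        return self.x0 + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y0 + self.n_rows * self.cell_size

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size ** 2 / 1e4

    def cell_index(self, x, y):
        """(col, row) of the cell containing each point (half-open rule).
        Indices may fall outside [0, n) for out-of-extent points."""
        i = np.floor((np.asarray(x, float) - self.x0) / self.cell_size).astype(int)
        j = np.floor((np.asarray(y, float) - self.y0) / self.cell_size).astype(int)
        return i, j

    def contains(self, x, y):
        i, j = self.cell_index(x, y)
        return (i >= 0) & (i < self.n_cols) & (j >= 0) & (j < self.n_rows)

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size


class UDRaster:
    """Gridded utilization distribution: nonnegative cell values on a Grid,
    with the fix count behind the surface (the population weighting key).

    ``values`` has shape (n_rows, n_cols); row 0 is the southern edge.
    """

    def __init__(self, grid: Grid, values: np.ndarray, n_fixes: int = 0):
        values = np.asarray(values, dtype=float)
        if values.shape != (grid.n_rows, grid.n_cols):
            raise ValueError(
                f"values shape {values.shape} != grid ({grid.n_rows}, {grid.n_cols})")
        if np.any(values < 0):
            raise ValueError("UD values must be nonnegative")
        self.grid = grid
        self.values = values
        self.n_fixes = int(n_fixes)

    def normalize(self) -> "UDRaster":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero UD")
        return UDRaster(self.grid, self.values / total, self.n_fixes)

    def sum(self) -> float:
        return float(self.values.sum())


# ---------------------------------------------------------------------------
# Telemetry CSV

def read_tracks(path) -> list[Track]:
    """Read Movebank-style telemetry CSV into one Track per individual.

    Required columns: individual-local-identifier, timestamp (ISO-8601 UTC),
    x, y (planar meters).  Optional: loc-error-sd (default 18 m).  Rows with
    missing coordinates are dropped (count logged); duplicate id+timestamp
    rows keep the first occurrence; fixes are sorted by time.
    """
    df = pd.read_csv(path)
    required = ["individual-local-identifier", "timestamp", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"telemetry CSV missing required columns: {missing}")

    n0 = len(df)
    df = df.dropna(subset=["x", "y"])
    if len(df) < n0:
        log.info("read_tracks: dropped %d rows with missing coordinates", n0 - len(df))

    try:
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # locate the offending row for the error message
        for row, v in zip(df.index, df["timestamp"]):
            try:
                pd.to_datetime(v, utc=True)
            except (ValueError, TypeError):
                raise ValueError(f"unparseable timestamp {v!r} at row {row}") from None
        raise
    df = df.assign(_t=ts.astype("int64") / 1e9)

    if "loc-error-sd" not in df.columns:
        df["loc-error-sd"] = DEFAULT_LOC_ERROR_SD

    df = df.sort_values(["individual-local-identifier", "_t"], kind="mergesort")
    before = len(df)
    df = df.drop_duplicates(subset=["individual-local-identifier", "_t"], keep="first")
    if len(df) < before:
        log.info("read_tracks: dropped %d duplicate-timestamp fixes", before - len(df))

    tracks = []
    for ind, g in df.groupby("individual-local-identifier", sort=True):
        tracks.append(Track(ind, g["_t"].to_numpy(), g["x"].to_numpy(),
                            g["y"].to_numpy(), g["loc-error-sd"].to_numpy()))
    log.info("read_tracks: %d tracks, %d fixes", len(tracks), len(df))
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    df = pd.concat([tr.to_dataframe() for tr in tracks], ignore_index=True)
    df.to_csv(path, index=False)
    log.info("write_tracks: wrote %d fixes to %s", len(df), path)


# ---------------------------------------------------------------------------
# Rasters

def write_raster(ud: UDRaster, path, fmt: str = "ascii-grid",
                 nodata: float = -9999.0) -> None:
    """Write a UD (or any gridded surface) to ESRI ASCII grid or GeoTIFF.

    Round-trip via read_raster reproduces values to 1e-9 relative and grid
    metadata exactly.  NaN cells are written as the ``nodata`` sentinel.
    """
    path = Path(path)
    g = ud.grid
    vals = np.where(np.isnan(ud.values), nodata, ud.values)
    if fmt == "ascii-grid":
        with open(path, "w") as fh:
            fh.write(f"ncols {g.n_cols}\n")
            fh.write(f"nrows {g.n_rows}\n")
            fh.write(f"xllcorner {float(g.x0)!r}\n")
            fh.write(f"yllcorner {float(g.y0)!r}\n")
            fh.write(f"cellsize {float(g.cell_size)!r}\n")
            fh.write(f"NODATA_value {float(nodata)!r}\n")
            fh.write(f"# n_fixes {ud.n_fixes}\n")
            # ESRI convention: first data row is the northern edge
            np.savetxt(fh, vals[::-1], fmt="%.17g")
    elif fmt == "geotiff":
        import tifffile
        meta = {"x0": g.x0, "y0": g.y0, "cell_size": g.cell_size,
                "n_fixes": ud.n_fixes, "nodata": nodata}
        tifffile.imwrite(path, vals[::-1].astype(np.float64),
                         description=json.dumps(meta))
    else:
        raise ValueError(f"unknown raster format {fmt!r}")
    log.info("write_raster: %s (%s, %dx%d)", path, fmt, g.n_rows, g.n_cols)


def read_raster(path, fmt: str | None = None) -> UDRaster:
    """Read a raster written by write_raster.  nodata cells become NaN."""
    path = Path(path)
    if fmt is None:
        fmt = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii-grid"
    if fmt == "ascii-grid":
        header: dict[str, float] = {}
        n_fixes = 0
        with open(path) as fh:
            lines = fh.readlines()
        data_start = 0
        for k, line in enumerate(lines):
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"):
                header[key] = float(parts[1])
                data_start = k + 1
            elif key == "#":
                if len(parts) >= 3 and parts[1] == "n_fixes":
                    n_fixes = int(parts[2])
                data_start = k + 1
            else:
                break
        vals = np.loadtxt(lines[data_start:], ndmin=2)[::-1]
        grid = Grid(header["xllcorner"], header["yllcorner"], header["cellsize"],
                    int(header["ncols"]), int(header["nrows"]))
        nodata = header.get("nodata_value", -9999.0)
    else:
        import tifffile
        with tifffile.TiffFile(path) as tf:
            vals = tf.asarray()[::-1]
            meta = json.loads(tf.pages[0].description)
        grid = Grid(meta["x0"], meta["y0"], meta["cell_size"],
                    vals.shape[1], vals.shape[0])
        n_fixes = meta.get("n_fixes", 0)
        nodata = meta.get("nodata", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    # UDRaster rejects negatives; keep NaN for nodata
    out = UDRaster.__new__(UDRaster)
    out.grid, out.values, out.n_fixes = grid, vals, int(n_fixes)
    return out


# ---------------------------------------------------------------------------
# Turbine points and wind-power-class raster

@dataclass
class TurbineSet:
    """Turbine point locations (planar meters) with total height (m AGL).

    ``height_m`` is NaN where the source lacked a height attribute; such
    turbines are excluded from height-filtered counts (and logged).
    """

    x: np.ndarray
    y: np.ndarray
    height_m: np.ndarray
    ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.height_m = np.asarray(self.height_m, float)
        if self.ids is None:
            self.ids = np.arange(len(self.x))
        if not (len(self.x) == len(self.y) == len(self.height_m) == len(self.ids)):
            raise ValueError("turbine arrays must have equal length")

    def __len__(self) -> int:
        return len(self.x)


def read_points(path) -> TurbineSet:
    """Read turbine points from GeoJSON (planar coordinates) or CSV
    (columns x, y, height_m)."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            gj = json.load(fh)
        xs, ys, hs, ids = [], [], [], []
        for k, feat in enumerate(gj.get("features", [])):
            cx, cy = feat["geometry"]["coordinates"][:2]
            props = feat.get("properties") or {}
            xs.append(cx)
            ys.append(cy)
            h = props.get("height_m")
            hs.append(np.nan if h is None else float(h))
            ids.append(props.get("id", k))
        ts = TurbineSet(np.array(xs), np.array(ys), np.array(hs), np.array(ids))
    else:
        df = pd.read_csv(path)
        for c in ("x", "y"):
            if c not in df.columns:
                raise ValueError(f"turbine CSV missing required column {c!r}")
        h = df["height_m"].to_numpy(float) if "height_m" in df.columns \
            else np.full(len(df), np.nan)
        ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))
        ts = TurbineSet(df["x"].to_numpy(float), df["y"].to_numpy(float), h, ids)
    n_noheight = int(np.isnan(ts.height_m).sum())
    if n_noheight:
        log.info("read_points: %d turbines lack a height attribute", n_noheight)
    log.info("read_points: %d turbines from %s", len(ts), path)
    return ts


def write_points(turbines: TurbineSet, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        feats = [{
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {"id": int(i) if np.issubdtype(type(i), np.integer) else i,
                           "height_m": None if np.isnan(h) else float(h)},
        } for x, y, h, i in zip(turbines.x, turbines.y, turbines.height_m,
                                turbines.ids)]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    else:
        pd.DataFrame({"id": turbines.ids, "x": turbines.x, "y": turbines.y,
                      "height_m": turbines.height_m}).to_csv(path, index=False)
    log.info("write_points: wrote %d turbines to %s", len(turbines), path)


def read_wpc(path) -> UDRaster:
    """Read a wind-power-class raster (integer classes 1-7) as a gridded
    surface.  Values are validated to lie in [1, 7] (NaN = nodata allowed)."""
    ras = read_raster(path)
    v = ras.values
    finite = v[np.isfinite(v)]
    if len(finite) and (finite.min() < 1 or finite.max() > 7
                        or np.any(finite != np.round(finite))):
        raise ValueError("WPC raster must hold integer classes in 1..7")
    return ras
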