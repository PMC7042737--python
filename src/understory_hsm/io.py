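"""Readers and writers for the plain-text formats the pipeline touches.

Point clouds are whitespace-delimited XYZ text (x, y, normalized height, one
point per line); rasters are ESRI ASCII grids; tables are CSV; settlement
points are CSV (x, y) or GeoJSON Point features.  All coordinates are assumed
to be in a projected metric CRS; the pipeline never reprojects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSpec, Raster

log = logging.getLogger(__name__)

__all__ = [
    "LidarPointSet",
    "read_point_cloud",
    "write_point_cloud",
    "read_raster",
    "write_raster",
    "read_nest_table",
    "write_nest_table",
    "read_points",
    "write_points_geojson",
]

#: height below which a negative normalized height is tolerated as DEM noise (m)
NEGATIVE_HEIGHT_TOLERANCE = 0.5

NEST_REQUIRED_COLUMNS = [
    "id",
    "x",
    "y",
    "year",
    "breeder_f",
    "breeder_m",
    "success",
    "renest_flag",
    "treated_flag",
    "area",
]


@dataclass
class LidarPointSet:
    """Height-normalized LiDAR returns: columns x, y, h (all metres)."""

    points: np.ndarray  # (n, 3) float64
    crs_note: str = "projected metric CRS (unspecified)"
    acquisition_window: tuple[str, str] | None = None
    flagged_negative: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        self.points = pts
        # heights slightly below zero are DEM noise; strongly negative ones are flagged
        self.flagged_negative = pts[:, 2] < -NEGATIVE_HEIGHT_TOLERANCE
        if self.flagged_negative.any():
            log.warning(
                "%d points with normalized height < -%.2f m (flagged, kept)",
                int(self.flagged_negative.sum()),
                NEGATIVE_HEIGHT_TOLERANCE,
            )

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def h(self) -> np.ndarray:
        return self.points[:, 2]


def read_point_cloud(path, fmt: str = "xyz_text") -> LidarPointSet:
    """Read a point cloud.  Only whitespace XYZ text is supported in this build.

    Malformed rows are a hard error naming the offending line; an empty file
    yields an empty point set with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "las":
        raise NotImplementedError(
            "LAS/LAZ reading is not supported in this build; convert to XYZ text"
        )
    if fmt != "xyz_text":
        raise ValueError(f"unknown point-cloud format {fmt!r}")

    rows: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate") from exc
    if not rows:
        log.warning("%s: empty point cloud", path)
        return LidarPointSet(np.empty((0, 3)))
    return LidarPointSet(np.array(rows, dtype=float))


def write_point_cloud(points: LidarPointSet, path) -> None:
    """Write XYZ text with full float precision (round-trip exact)."""
    with open(path, "w") as fh:
        for x, y, h in points.points:
            fh.write(f"{float(x)!r} {float(y)!r} {float(h)!r}\n")


def read_raster(path) -> Raster:
    """Read an ESRI ASCII grid (single band, square cells, metric coordinates)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in (
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing header field {req}")
    cell = header["cellsize"]
    x0, y0 = header["xllcorner"], header["yllcorner"]
    _reject_geographic(x0, y0, cell, path)
    nx, ny = int(header["ncols"]), int(header["nrows"])
    flat = np.array(" ".join(data_lines).split(), dtype=float)
    if flat.size != nx * ny:
        raise ValueError(f"{path}: expected {nx * ny} values, found {flat.size}")
    values = flat.reshape(ny, nx)
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    # ESRI ASCII stores rows top-down; internal convention is bottom-up
    values = values[::-1].copy()
    return Raster(values, GridSpec(x0=x0, y0=y0, cell=cell, nx=nx, ny=ny))


def _reject_geographic(x0: float, y0: float, cell: float, path) -> None:
    if cell < 0.5 and abs(x0) <= 360 and abs(y0) <= 90:
        raise ValueError(
            f"{path}: cell size {cell} with degree-sized coordinates looks like a "
            "geographic CRS; reproject to a projected metric CRS first"
        )


def write_raster(raster: Raster, path, nodata_value: float = -9999.0) -> None:
    """Write an ESRI ASCII grid; full float precision so round-trips are exact."""
    spec = raster.spec
    values = raster.values[::-1]  # top-down on disk
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.nx}\n")
        fh.write(f"nrows {spec.ny}\n")
        fh.write(f"xllcorner {float(spec.x0)!r}\n")
        fh.write(f"yllcorner {float(spec.y0)!r}\n")
        fh.write(f"cellsize {float(spec.cell)!r}\n")
        fh.write(f"NODATA_value {float(nodata_value)!r}\n")
        for row in values:
            out = np.where(np.isnan(row), nodata_value, row)
            fh.write(" ".join(repr(float(v)) for v in out) + "\n")


def read_nest_table(path) -> pd.DataFrame:
    """Read the breeding-event table.

    Required columns: id, x, y, year, breeder_f, breeder_m, success,
    renest_flag, treated_flag, area.  ``success`` must already be coded 0/1;
    anything else is rejected rather than guessed at.  Missing optional
    columns come back absent; missing flag values are treated as false.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in NEST_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    success = pd.to_numeric(df["success"], errors="coerce")
    bad = ~success.isin([0, 1]) | success.isna()
    if bad.any():
        raise ValueError(
            f"{path}: success must be coded 0/1; offending rows "
            f"{df.index[bad].tolist()[:5]}"
        )
    df["success"] = success.astype(int)
    for flag in ("renest_flag", "treated_flag"):
        df[flag] = df[flag].fillna(False).astype(bool)
    df["year"] = df["year"].astype(int)
    return df


def write_nest_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_points(path) -> np.ndarray:
    """Read a point set (settlements) from CSV (columns x, y) or GeoJSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".json", ".geojson"):
        with open(path) as fh:
            gj = json.load(fh)
        coords = []
        for feat in gj.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ValueError(f"{path}: only Point features are supported")
            coords.append(tuple(geom["coordinates"][:2]))
        return np.array(coords, dtype=float).reshape(-1, 2)
    df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: point CSV needs columns x, y")
    return df[["x", "y"]].to_numpy(dtype=float)


def write_points_geojson(points: np.ndarray, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
            "properties": {},
        }
        for x, y in np.asarray(points, dtype=float).reshape(-1, 2)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
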