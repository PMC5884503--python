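"""Core data types, file I/O, response transforms, depth-weighted soil
integration, and the Pearson correlation screen.

Grid convention: north-up, row-major, cell-center sampling.  The origin
``(x_origin, y_origin)`` is the *top-left corner* of the grid; cell
``(row, col)`` has its center at ``(x_origin + (col + 0.5) * cell_size,
y_origin - (row + 0.5) * cell_size)``.

Rasters are stored as one plain-text ESRI ASCII grid (``.asc``) per layer
plus a JSON sidecar naming the layers and recording the shared geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneracyError, DomainError, FormatError, GeometryError

RESERVED_COLUMNS = ("site_id", "x", "y", "phytolith_pct")

#: thickness (cm) of the three soil depth intervals 0-5, 5-15, 15-30 cm;
#: depth-weighted averaging weights by these thicknesses ("by volume" with
#: constant area).
DEPTH_WEIGHTS = (5.0, 10.0, 15.0)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

NODATA = -9999.0


# ---------------------------------------------------------------------------
# grid geometry


@dataclass(frozen=True)
class GridGeometry:
    """Shared geometry of a raster grid (north-up, row-major)."""

    rows: int
    cols: int
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 1.0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise GeometryError(f"grid must be at least 1x1, got {self.rows}x{self.cols}")
        if self.cell_size <= 0:
            raise GeometryError(f"cell size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate grids of all cell centers."""
        xs = self.x_origin + (np.arange(self.cols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(self.rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col); raises if outside the grid."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y)) / self.cell_size).astype(int)
        if np.any((col < 0) | (col >= self.cols) | (row < 0) | (row >= self.rows)):
            raise GeometryError("coordinates fall outside the grid")
        return row, col


def _check_same_geometry(a: GridGeometry, b: GridGeometry) -> None:
    if a != b:
        raise GeometryError(f"geometry mismatch: {a} vs {b}")


# ---------------------------------------------------------------------------
# GridMap / CovariateStack


@dataclass
class GridMap:
    """A single output grid (prediction, novelty distance, residual, mask)."""

    values: np.ndarray
    mask: np.ndarray  # True where the cell is valid
    geometry: GridGeometry
    name: str = "map"
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.geometry.shape or self.mask.shape != self.geometry.shape:
            raise GeometryError("values/mask shape does not match geometry")

    def copy(self) -> "GridMap":
        return GridMap(self.values.copy(), self.mask.copy(), self.geometry, self.name, self.units)

    def masked(self) -> np.ndarray:
        out = self.values.copy()
        out[~self.mask] = np.nan
        return out


class CovariateStack:
    """Named, co-registered covariate grids with a shared missing-data mask."""

    def __init__(
        self,
        layers: dict[str, np.ndarray],
        geometry: GridGeometry,
        mask: np.ndarray | None = None,
    ):
        if not layers:
            raise GeometryError("stack must contain at least one layer")
        self.geometry = geometry
        self.layers: dict[str, np.ndarray] = {}
        for name, grid in layers.items():
            grid = np.asarray(grid, dtype=float)
            if grid.shape != geometry.shape:
                raise GeometryError(f"layer '{name}' shape {grid.shape} != {geometry.shape}")
            self.layers[name] = grid
        if mask is None:
            mask = np.ones(geometry.shape, dtype=bool)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != geometry.shape:
            raise GeometryError("mask shape does not match geometry")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def as_map(self, name: str) -> GridMap:
        return GridMap(self.layers[name], self.mask, self.geometry, name=name)

    def table(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Valid cells as a DataFrame (row-major order), one column per layer."""
        variables = list(variables) if variables is not None else self.layer_names
        missing = [v for v in variables if v not in self.layers]
        if missing:
            raise GeometryError(f"stack is missing layers: {missing}")
        sel = self.mask.ravel()
        return pd.DataFrame({v: self.layers[v].ravel()[sel] for v in variables})

    def values_at(self, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        """Layer values at the cells containing coordinates (x, y)."""
        row, col = self.geometry.cell_index(x, y)
        return pd.DataFrame({name: grid[row, col] for name, grid in self.layers.items()})


# ---------------------------------------------------------------------------
# SiteTable


class SiteTable:
    """Per-site coordinates, covariates, and (optional) phytolith response.

    Backed by a DataFrame with reserved columns ``site_id``, ``x``, ``y``
    and optionally ``phytolith_pct``; all other columns are covariates.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy().reset_index(drop=True)
        for col in ("site_id", "x", "y"):
            if col not in frame.columns:
                raise FormatError(f"site table missing required column '{col}'")
        if frame["site_id"].duplicated().any():
            dups = frame.loc[frame["site_id"].duplicated(), "site_id"].tolist()
            raise FormatError(f"duplicate site_id values: {dups}")
        if "phytolith_pct" in frame.columns:
            p = frame["phytolith_pct"]
            bad = p.notna() & (p <= 0)
            if bad.any():
                rows = frame.index[bad].tolist()
                raise FormatError(f"non-positive phytolith_pct at rows {rows}")
        self.frame = frame

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def site_ids(self) -> np.ndarray:
        return self.frame["site_id"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy(dtype=float)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in RESERVED_COLUMNS]

    @property
    def has_response(self) -> bool:
        return "phytolith_pct" in self.frame.columns and self.frame["phytolith_pct"].notna().all()

    @property
    def response(self) -> np.ndarray:
        """Phytolith content, percent dry soil mass."""
        if not self.has_response:
            raise DomainError("site table has no (complete) phytolith response")
        return self.frame["phytolith_pct"].to_numpy(dtype=float)

    @property
    def log_response(self) -> np.ndarray:
        return log_transform(self.response)

    def covariate_matrix(self, variables: Sequence[str] | None = None) -> np.ndarray:
        variables = list(variables) if variables is not None else self.covariate_names
        missing = [v for v in variables if v not in self.frame.columns]
        if missing:
            raise FormatError(f"site table missing covariates: {missing}")
        return self.frame[variables].to_numpy(dtype=float)

    def with_response(self, phytolith_pct: np.ndarray) -> "SiteTable":
        frame = self.frame.copy()
        frame["phytolith_pct"] = np.asarray(phytolith_pct, dtype=float)
        return SiteTable(frame)

    def subset(self, index: np.ndarray) -> "SiteTable":
        return SiteTable(self.frame.iloc[np.asarray(index)])

    def restrict(self, covariate: str, max_value: float) -> "SiteTable":
        """Sites with ``covariate <= max_value`` (e.g. coast_distance <= 75 km)."""
        if covariate not in self.frame.columns:
            raise FormatError(f"unknown covariate '{covariate}'")
        keep = self.frame[covariate].to_numpy(dtype=float) <= max_value
        return SiteTable(self.frame.loc[keep])


# ---------------------------------------------------------------------------
# site CSV I/O


def read_sites(path: str | Path) -> SiteTable:
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse site CSV {path}: {exc}") from exc
    return SiteTable(frame)


def write_sites(table: SiteTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid + JSON sidecar)


def _write_asc(values: np.ndarray, mask: np.ndarray, geom: GridGeometry, path: Path) -> None:
    out = values.astype(float).copy()
    out[~mask | ~np.isfinite(out)] = NODATA
    yll = geom.y_origin - geom.rows * geom.cell_size
    header = (
        f"ncols {geom.cols}\n"
        f"nrows {geom.rows}\n"
        f"xllcorner {geom.x_origin:.10g}\n"
        f"yllcorner {yll:.10g}\n"
        f"cellsize {geom.cell_size:.10g}\n"
        f"NODATA_value {NODATA:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def _read_asc(path: Path) -> tuple[np.ndarray, np.ndarray, GridGeometry]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        body = np.loadtxt(fh, ndmin=2)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if body.shape != (rows, cols):
        raise FormatError(f"{path}: grid body {body.shape} != header {(rows, cols)}")
    cell = header["cellsize"]
    geom = GridGeometry(
        rows=rows,
        cols=cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + rows * cell,
        cell_size=cell,
    )
    nodata = header.get("nodata_value", NODATA)
    mask = body != nodata
    values = body.copy()
    values[~mask] = np.nan
    return values, mask, geom


def write_stack(stack: CovariateStack, directory: str | Path) -> None:
    """One single-band ``.asc`` per layer plus a ``stack.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.layers.items():
        _write_asc(grid, stack.mask, stack.geometry, directory / f"{name}.asc")
    sidecar = {
        "layers": stack.layer_names,
        "geometry": {
            "rows": stack.geometry.rows,
            "cols": stack.geometry.cols,
            "x_origin": stack.geometry.x_origin,
            "y_origin": stack.geometry.y_origin,
            "cell_size": stack.geometry.cell_size,
        },
    }
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_stack(directory: str | Path) -> CovariateStack:
    directory = Path(directory)
    sidecar_path = directory / "stack.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    layers: dict[str, np.ndarray] = {}
    geom: GridGeometry | None = None
    mask: np.ndarray | None = None
    for name in sidecar["layers"]:
        values, layer_mask, layer_geom = _read_asc(directory / f"{name}.asc")
        if geom is None:
            geom, mask = layer_geom, layer_mask
        else:
            _check_same_geometry(geom, layer_geom)
            mask = mask & layer_mask
        layers[name] = np.nan_to_num(values, nan=0.0)
    return CovariateStack(layers, geom, mask)


def write_map(gmap: GridMap, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_asc(gmap.values, gmap.mask, gmap.geometry, path)
    meta = {"name": gmap.name, "units": gmap.units}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_map(path: str | Path) -> GridMap:
    path = Path(path)
    values, mask, geom = _read_asc(path)
    name, units = path.stem, ""
    meta_path = path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        name = meta.get("name", name)
        units = meta.get("units", units)
    return GridMap(np.nan_to_num(values, nan=0.0), mask, geom, name=name, units=units)


# ---------------------------------------------------------------------------
# transforms


def log_transform(p):
    """Natural log of phytolith content; defined only for p > 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or not np.all(np.isfinite(p)):
        raise DomainError("log transform requires strictly positive finite values")
    return np.log(p)


def back_transform(y):
    """Inverse of :func:`log_transform` (naive exponential)."""
    return np.exp(np.asarray(y, dtype=float))


def depth_weighted_average(v1, v2, v3):
    """Integrate values at 0-5, 5-15 and 15-30 cm into one value.

    Weights are the layer thicknesses (5, 10, 15 cm), i.e. a by-volume
    weighted mean over the 0-30 cm column.
    """
    v1, v2, v3 = (np.asarray(v, dtype=float) for v in (v1, v2, v3))
    if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2)) and np.all(np.isfinite(v3))):
        raise DomainError("depth-weighted average requires finite inputs")
    w1, w2, w3 = DEPTH_WEIGHTS
    total = w1 + w2 + w3
    result = (w1 * v1 + w2 * v2 + w3 * v3) / total
    return float(result) if result.ndim == 0 else result


# ---------------------------------------------------------------------------
# correlation screen


def stars_for_p(p: float) -> str:
    """Significance stars: * <= .05, ** <= .01, *** <= .001."""
    if not np.isfinite(p):
        return ""
    for threshold, symbol in STAR_THRESHOLDS:
        if p <= threshold:
            return symbol
    return ""


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p from the t distribution with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise DegeneracyError("need at least 3 observations for a correlation test")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegeneracyError("zero-variance input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_screen(
    sites: SiteTable,
    response: str = "phytolith_pct",
    restrict: tuple[str, float] | Callable[[pd.DataFrame], np.ndarray] | None = None,
    variables: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each covariate against a response column.

    ``restrict`` limits the screen to a subset of sites: either a
    ``(covariate, max_value)`` threshold (e.g. ``("coast_distance", 75000)``
    for the restricted-range variant) or a boolean predicate on the frame.

    Returns a DataFrame with columns variable, r, p, stars, n, degenerate.
    Zero-variance variables are flagged, not silently reported as 0.
    """
    frame = sites.frame
    if response not in frame.columns:
        raise FormatError(f"unknown response column '{response}'")
    if restrict is not None:
        if callable(restrict):
            keep = np.asarray(restrict(frame), dtype=bool)
        else:
            cov, max_value = restrict
            if cov not in frame.columns:
                raise FormatError(f"unknown restriction covariate '{cov}'")
            keep = frame[cov].to_numpy(dtype=float) <= max_value
        frame = frame.loc[keep]
    if len(frame) < 3:
        raise DegeneracyError(f"only {len(frame)} sites after restriction; need >= 3")
    y = frame[response].to_numpy(dtype=float)
    variables = list(variables) if variables is not None else [
        c for c in frame.columns if c not in RESERVED_COLUMNS and c != response
    ]
    records = []
    for var in variables:
        x = frame[var].to_numpy(dtype=float)
        try:
            r, p = pearson_with_p(x, y)
            degenerate = False
        except DegeneracyError:
            r, p, degenerate = math.nan, math.nan, True
        records.append(
            {
                "variable": var,
                "r": r,
                "p": p,
                "stars": stars_for_p(p),
                "n": len(frame),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame.from_records(records)
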