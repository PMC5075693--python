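"""Raster, sample-table and model-file input/output.

Rasters are exchanged as ESRI ASCII grids (``.asc``, plain text) or
single-band GeoTIFFs; all grids live in geographic coordinates (decimal
degrees, WGS84-style), matching the 30-arc-second bioclim layout, and no
reprojection is attempted. Grid convention: row 0 is the northernmost
row, cells are addressed (row, col) 0-based, and a point belongs to the
cell containing it under half-open intervals [x0, x0 + dx).

Classic bioclim distributions store temperatures as °C × 10; the stack
reader accepts a per-variable scale factor (default 1.0) so both scaled
archives and unscaled synthetic grids can be read with explicit intent.

Sample tables are CSV with columns ``site_id, lon, lat, content`` (and
optional ``elev``); ``content`` is schisantherin-A content in percent.
Fitted models round-trip through a JSON document holding the membership
function per variable, the weight vector and the content-normalization
constant ``c_max``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import AlignmentError, SchemaError, ValidationError
from .membership import membership_from_dict, membership_to_dict
from .reference import BIOCLIM_CODES
from .weighting import WeightVector

logger = logging.getLogger("habisuit")

#: sentinel written for nodata cells in float rasters
DEFAULT_NODATA = -9999.0

_GEOTRANSFORM_TOL = 1e-9

# GeoTIFF tag ids: pixel scale, tiepoint, GDAL nodata
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine georeferencing: ``x0, y0`` are the coordinates of the
    top-left (north-west) corner; ``dx, dy`` are positive cell sizes in
    decimal degrees."""

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.x0, self.y0, self.dx, self.dy)):
            raise ValidationError("geotransform values must be finite")
        if self.dx <= 0 or self.dy <= 0:
            raise ValidationError("cell sizes must be positive")

    def cell_index(self, lon: float, lat: float, shape: tuple[int, int]):
        """(row, col) of the cell containing a point, or None when outside
        the grid. Half-open convention: a point on a west/north cell edge
        belongs to that cell."""
        col = math.floor((lon - self.x0) / self.dx)
        row = math.floor((self.y0 - lat) / self.dy)
        nrows, ncols = shape
        if 0 <= row < nrows and 0 <= col < ncols:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x0 + (col + 0.5) * self.dx,
            self.y0 - (row + 0.5) * self.dy,
        )

    def approx_equal(self, other: "GeoTransform", tol: float = _GEOTRANSFORM_TOL):
        return (
            abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass
class BioclimStack:
    """Co-registered stack of named bioclimatic layers.

    ``layers`` maps variable codes to 2-D float grids; ``nodata_mask`` is
    True where any layer lacks data (the union of per-layer nodata), and
    is shared by all layers.
    """

    layers: dict[str, np.ndarray]
    transform: GeoTransform
    nodata_mask: np.ndarray
    crs_label: str = "EPSG:4326"

    def __post_init__(self):
        if not self.layers:
            raise ValidationError("stack has no layers")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise AlignmentError(f"layers have mismatched shapes: {shapes}")
        (shape,) = shapes
        if self.nodata_mask.shape != shape:
            raise AlignmentError("nodata mask shape does not match layers")
        unknown = set(self.layers) - set(BIOCLIM_CODES)
        if unknown:
            raise ValidationError(f"unknown variable codes: {sorted(unknown)}")
        self.nodata_mask = self.nodata_mask.astype(bool)
        self.layers = {c: np.asarray(a, dtype=float) for c, a in self.layers.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.layers)

    @property
    def n_valid(self) -> int:
        return int((~self.nodata_mask).sum())

    def layer(self, code: str) -> np.ndarray:
        try:
            return self.layers[code]
        except KeyError as exc:
            raise ValidationError(f"stack has no layer {code!r}") from exc

    def values_at(self, lons, lats, codes: Sequence[str] | None = None):
        """Per-site variable values.

        Returns ``(values, inside)`` where ``values`` is an
        (n_sites, n_codes) array (NaN for sites outside the grid or on
        nodata cells) and ``inside`` is the boolean mask of usable sites.
        """
        codes = self.codes if codes is None else tuple(codes)
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        values = np.full((lons.size, len(codes)), np.nan)
        inside = np.zeros(lons.size, dtype=bool)
        for i, (lon, lat) in enumerate(zip(lons, lats)):
            idx = self.transform.cell_index(lon, lat, self.shape)
            if idx is None or self.nodata_mask[idx]:
                continue
            inside[i] = True
            values[i] = [self.layers[c][idx] for c in codes]
        return values, inside

    def with_layers(self, layers: dict[str, np.ndarray]) -> "BioclimStack":
        return BioclimStack(
            layers=layers,
            transform=self.transform,
            nodata_mask=self.nodata_mask.copy(),
            crs_label=self.crs_label,
        )


# ---------------------------------------------------------------------------
# raster files
# ---------------------------------------------------------------------------

@dataclass
class RasterData:
    """A single raster band with georeferencing, as read from disk."""

    values: np.ndarray
    transform: GeoTransform
    nodata_mask: np.ndarray
    nodata_value: float = DEFAULT_NODATA


def read_raster(path) -> RasterData:
    """Read a single-band raster (.asc ESRI ASCII grid or .tif GeoTIFF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        return _read_ascii_grid(path)
    if suffix in (".tif", ".tiff"):
        return _read_geotiff(path)
    raise ValidationError(f"unsupported raster extension {suffix!r} (use .asc or .tif)")


def write_raster(path, values, transform: GeoTransform, nodata_mask=None,
                 nodata_value: float = DEFAULT_NODATA) -> Path:
    """Write a single-band raster; dialect chosen from the extension."""
    path = Path(path)
    values = np.asarray(values)
    if nodata_mask is None:
        nodata_mask = ~np.isfinite(values.astype(float))
    suffix = path.suffix.lower()
    if suffix == ".asc":
        _write_ascii_grid(path, values, transform, nodata_mask, nodata_value)
    elif suffix in (".tif", ".tiff"):
        _write_geotiff(path, values, transform, nodata_mask, nodata_value)
    else:
        raise ValidationError(
            f"unsupported raster extension {suffix!r} (use .asc or .tif)")
    return path


def _read_ascii_grid(path: Path) -> RasterData:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value", "xllcenter", "yllcenter", "dx", "dy",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            if key == "cellsize" and "dx" in header and "dy" in header:
                continue
            raise SchemaError(f"ASCII grid {path} missing header field {key}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        raise SchemaError(
            f"ASCII grid {path}: data shape {data.shape} does not match header "
            f"({nrows}, {ncols})")
    dx = header.get("dx", header.get("cellsize"))
    dy = header.get("dy", header.get("cellsize"))
    if "xllcorner" in header:
        x0 = header["xllcorner"]
    elif "xllcenter" in header:
        x0 = header["xllcenter"] - dx / 2
    else:
        raise SchemaError(f"ASCII grid {path} missing xllcorner")
    if "yllcorner" in header:
        yll = header["yllcorner"]
    elif "yllcenter" in header:
        yll = header["yllcenter"] - dy / 2
    else:
        raise SchemaError(f"ASCII grid {path} missing yllcorner")
    y0 = yll + nrows * dy
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    mask = np.isclose(data, nodata) | ~np.isfinite(data)
    return RasterData(data, GeoTransform(x0, y0, dx, dy), mask, nodata)


def _write_ascii_grid(path, values, transform, nodata_mask, nodata_value):
    values = np.asarray(values, dtype=float).copy()
    nrows, ncols = values.shape
    values[np.asarray(nodata_mask, dtype=bool)] = nodata_value
    yll = float(transform.y0 - nrows * transform.dy)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(transform.x0)!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        if abs(transform.dx - transform.dy) <= _GEOTRANSFORM_TOL:
            fh.write(f"cellsize {float(transform.dx)!r}\n")
        else:
            fh.write(f"dx {float(transform.dx)!r}\n")
            fh.write(f"dy {float(transform.dy)!r}\n")
        fh.write(f"NODATA_value {float(nodata_value)!r}\n")
        for row in values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_geotiff(path: Path) -> RasterData:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = np.asarray(page.asarray(), dtype=float)
        if data.ndim != 2:
            raise SchemaError(f"GeoTIFF {path} is not single-band")
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise SchemaError(f"GeoTIFF {path} lacks georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        # tiepoint (i, j, k, x, y, z) anchors raster pixel (i, j) at (x, y)
        i, j = tie[0], tie[1]
        x0 = tie[3] - i * sx
        y0 = tie[4] + j * sy
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    mask = np.isclose(data, nodata) | ~np.isfinite(data)
    return RasterData(data, GeoTransform(x0, y0, sx, sy), mask, nodata)


def _write_geotiff(path, values, transform, nodata_mask, nodata_value):
    values = np.asarray(values)
    out = values.astype(np.float32 if values.dtype.kind == "f" else values.dtype)
    if out.dtype.kind == "f":
        out = out.copy()
        out[np.asarray(nodata_mask, dtype=bool)] = nodata_value
    else:
        out = out.copy()
        out[np.asarray(nodata_mask, dtype=bool)] = int(nodata_value)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (transform.dx, transform.dy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata_value)),
    ]
    tifffile.imwrite(path, out, extratags=extratags)


def read_stack(paths: Mapping[str, "str | Path"] | Iterable,
               codes: Sequence[str] | None = None,
               scale_factors: Mapping[str, float] | None = None) -> BioclimStack:
    """Read co-registered rasters into a stack.

    Parameters
    ----------
    paths : mapping code -> file path, or an iterable of paths zipped with
        ``codes``
    codes : required when ``paths`` is a plain iterable
    scale_factors : optional per-code multiplier applied on read (e.g. 0.1
        for archives storing temperature as °C × 10)

    Raises
    ------
    AlignmentError when grids disagree in shape or geotransform.
    """
    if isinstance(paths, Mapping):
        pairs = list(paths.items())
    else:
        paths = list(paths)
        if codes is None:
            raise ValidationError("codes are required when paths is not a mapping")
        if len(codes) != len(paths):
            raise ValidationError("codes and paths must have equal length")
        pairs = list(zip(codes, paths))
    unknown = {c for c, _ in pairs} - set(BIOCLIM_CODES)
    if unknown:
        raise ValidationError(f"unknown variable codes: {sorted(unknown)}")
    scale_factors = dict(scale_factors or {})

    layers: dict[str, np.ndarray] = {}
    transform: GeoTransform | None = None
    mask: np.ndarray | None = None
    for code, path in pairs:
        rast = read_raster(path)
        if transform is None:
            transform, mask = rast.transform, rast.nodata_mask.copy()
        else:
            if rast.values.shape != next(iter(layers.values())).shape:
                raise AlignmentError(
                    f"layer {code}: shape {rast.values.shape} does not match stack")
            if not rast.transform.approx_equal(transform):
                raise AlignmentError(
                    f"layer {code}: geotransform does not match stack")
            mask |= rast.nodata_mask
        layers[code] = rast.values * scale_factors.get(code, 1.0)
    return BioclimStack(layers=layers, transform=transform, nodata_mask=mask)


def write_surface(surface, path, nodata_value: float | None = None) -> Path:
    """Write a suitability surface (float) or grade map (integer codes).

    The object must expose ``values`` (or ``grades``), ``transform`` and
    ``nodata_mask``. Grade maps are written as integer bands with nodata
    sentinel 255; float surfaces use the declared float sentinel.
    """
    grades = getattr(surface, "grades", None)
    if grades is not None:
        sentinel = 255 if nodata_value is None else nodata_value
        return write_raster(path, grades.astype(np.uint8), surface.transform,
                            surface.nodata_mask, sentinel)
    values = surface.values
    sentinel = DEFAULT_NODATA if nodata_value is None else nodata_value
    return write_raster(path, values, surface.transform, surface.nodata_mask,
                        sentinel)


# ---------------------------------------------------------------------------
# sample tables
# ---------------------------------------------------------------------------

@dataclass
class SampleSet:
    """Site records: unique ``site_id``, coordinates in decimal degrees and
    schisantherin-A content in percent (optional elevation in metres)."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("site_id", "lon", "lat", "content")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"sample table missing column(s): {missing}")
        t = self.table.reset_index(drop=True).copy()
        t["site_id"] = t["site_id"].astype(str)
        for col in ("lon", "lat", "content"):
            t[col] = pd.to_numeric(t[col], errors="raise")
        if t["site_id"].duplicated().any():
            dups = t.loc[t["site_id"].duplicated(), "site_id"].tolist()
            raise ValidationError(f"duplicate site_id(s): {dups[:5]}")
        if not np.isfinite(t[["lon", "lat"]].to_numpy()).all():
            raise ValidationError("coordinates must be finite")
        if (t["content"] < 0).any():
            raise ValidationError("content must be nonnegative")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def lons(self) -> np.ndarray:
        return self.table["lon"].to_numpy(dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return self.table["lat"].to_numpy(dtype=float)

    @property
    def contents(self) -> np.ndarray:
        return self.table["content"].to_numpy(dtype=float)

    @property
    def site_ids(self) -> list[str]:
        return self.table["site_id"].tolist()

    def subset(self, index) -> "SampleSet":
        return SampleSet(self.table.iloc[np.asarray(index)].reset_index(drop=True))


def read_samples(path) -> SampleSet:
    """Read a sample CSV; rows with missing content are dropped (logged)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SampleSet.REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"sample CSV {path} missing column(s): {missing}")
    n_blank = int(df["content"].isna().sum())
    if n_blank:
        logger.warning("read_samples: dropping %d row(s) with missing content",
                       n_blank)
        df = df[df["content"].notna()]
    return SampleSet(df)


def write_samples(samples: SampleSet, path) -> Path:
    path = Path(path)
    samples.table.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------

MODEL_FORMAT = "habisuit-model"
MODEL_FORMAT_VERSION = 1


def save_model(model, path, seed: int | None = None,
               fit_results: Mapping[str, object] | None = None) -> Path:
    """Serialize a fitted SuitabilityModel (plus metadata) to JSON."""
    from . import __version__

    variables = []
    for code, f in model.functions.items():
        entry = {"code": code, **membership_to_dict(f)}
        if fit_results and code in fit_results:
            fr = fit_results[code]
            entry["fitting_degree"] = fr.fitting_degree
            entry["residual_rmse"] = fr.residual_rmse
            entry["n_points"] = fr.n_points
        variables.append(entry)
    doc = {
        "format": MODEL_FORMAT,
        "format_version": MODEL_FORMAT_VERSION,
        "software_version": __version__,
        "seed": seed,
        "c_max": model.c_max,
        "variables": variables,
        "weights": dict(model.weights.weights),
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2))
    return path


def load_model(path):
    """Load a SuitabilityModel from its JSON document (lossless round-trip)."""
    from .suitability import SuitabilityModel

    doc = json.loads(Path(path).read_text())
    if doc.get("format") != MODEL_FORMAT:
        raise SchemaError(f"{path} is not a {MODEL_FORMAT} file")
    functions = {v["code"]: membership_from_dict(v) for v in doc["variables"]}
    weights = WeightVector(doc["weights"])
    return SuitabilityModel(functions=functions, weights=weights,
                            c_max=float(doc["c_max"]))
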