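"""Reflectance-cube and region I/O plus band bookkeeping.

Cubes are stored as ENVI-style rasters: a flat band-sequential binary
file next to a plain-text ``.hdr`` carrying the grid, the CRS label and
per-band center wavelengths.  Regions are GeoJSON feature collections
whose features carry a ``class_code`` property.  Wavelengths may also be
supplied as a two-column CSV sidecar (band_index, wavelength_nm).

Pixel convention: indices are 0-based; pixel (row, col) covers the
half-open square [x0 + col*sx, x0 + (col+1)*sx) x (y0 + (row+1)*sy,
y0 + row*sy] for a north-up transform (sy < 0); pixel centers sit at
the half-integer offsets.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Affine",
    "BandDef",
    "SensorModel",
    "Scene",
    "ClassRegion",
    "GridDefinition",
    "read_scene",
    "write_scene",
    "read_regions",
    "write_regions",
    "drop_overlap_bands",
    "resample_nearest",
]

DEFAULT_OVERLAP_TOLERANCE_NM = 0.5


@dataclass(frozen=True)
class Affine:
    """Row-major 2-D affine georeference: (x, y) = T @ (col, row, 1).

    Mirrors the conventional six-parameter layout (a, b, c, d, e, f)
    where c, f are the coordinates of the raster's top-left corner.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, xsize: float, ysize: float) -> "Affine":
        """North-up transform with pixel width xsize and height ysize (> 0)."""
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    def __mul__(self, colrow: tuple[float, float]) -> tuple[float, float]:
        col, row = colrow
        return (
            self.a * col + self.b * row + self.c,
            self.d * col + self.e * row + self.f,
        )

    def invert(self) -> "Affine":
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("transform is not invertible")
        ia, ib = self.e / det, -self.b / det
        id_, ie = -self.d / det, self.a / det
        ic = -(ia * self.c + ib * self.f)
        if_ = -(id_ * self.c + ie * self.f)
        return Affine(ia, ib, ic, id_, ie, if_)

    def pixel_centers(self, rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of every pixel center as (xs, ys) 2-D arrays."""
        jj, ii = np.meshgrid(np.arange(cols) + 0.5, np.arange(rows) + 0.5)
        xs = self.a * jj + self.b * ii + self.c
        ys = self.d * jj + self.e * ii + self.f
        return xs, ys

    def to_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)


@dataclass(frozen=True)
class BandDef:
    """One spectral band: 0-based ordinal, center wavelength, detector tag."""

    index: int
    center_nm: float
    detector: str
    name: str | None = None

    def __post_init__(self) -> None:
        if self.center_nm <= 0:
            raise ValueError(f"center wavelength must be positive, got {self.center_nm}")
        if self.detector not in ("VNIR", "SWIR", "MSI"):
            raise ValueError(f"unknown detector tag {self.detector!r}")


@dataclass(frozen=True)
class SensorModel:
    """Named ordered band set at a stated ground resolution."""

    name: str
    bands: tuple[BandDef, ...]
    ground_resolution_m: float

    def __post_init__(self) -> None:
        if self.ground_resolution_m <= 0:
            raise ValueError("ground resolution must be positive")
        indices = [b.index for b in self.bands]
        if indices != list(range(len(self.bands))):
            raise ValueError("band indices must be contiguous from 0 in list order")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return np.array([b.center_nm for b in self.bands], dtype=float)

    def subset(self, keep: Sequence[int]) -> "SensorModel":
        """New model with the given band positions, reindexed from 0."""
        new = tuple(
            replace(self.bands[i], index=j) for j, i in enumerate(keep)
        )
        return SensorModel(self.name, new, self.ground_resolution_m)


@dataclass
class Scene:
    """A georeferenced reflectance cube bound to a sensor model.

    ``values`` has shape (rows, cols, bands); band order matches
    ``sensor.bands``.  Reflectance is nominally in [0, 1]; out-of-range
    values are permitted but reported by :meth:`validate`.
    """

    values: np.ndarray
    transform: Affine
    crs: str
    sensor: SensorModel
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("scene values must be a rows x cols x bands array")
        if self.values.shape[2] != self.sensor.n_bands:
            raise ValueError(
                f"band count mismatch: cube has {self.values.shape[2]} bands, "
                f"sensor defines {self.sensor.n_bands}"
            )
        self.transform.invert()  # raises if singular

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def validate(self) -> dict:
        """QC summary: counts of nodata and out-of-range pixels."""
        valid = self.values != self.nodata
        out_of_range = int(np.sum(valid & ((self.values < 0) | (self.values > 1))))
        return {
            "n_nodata": int(np.sum(~valid)),
            "n_out_of_range": out_of_range,
        }


@dataclass(frozen=True)
class ClassRegion:
    """A labeled polygon in scene coordinates."""

    geometry: BaseGeometry
    class_code: str
    region_id: str

    def __post_init__(self) -> None:
        if self.geometry.is_empty or not self.geometry.is_valid:
            raise ValueError(f"region {self.region_id}: geometry is empty or invalid")


@dataclass(frozen=True)
class GridDefinition:
    """Target grid for resampling: shape plus georeference."""

    rows: int
    cols: int
    transform: Affine
    crs: str


# ---------------------------------------------------------------------------
# ENVI-style raster I/O

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _parse_envi_header(text: str) -> dict:
    """Parse 'key = value' lines; brace-delimited lists may span lines."""
    fields: dict[str, str] = {}
    # strip the ENVI magic line, keep the rest as one string
    body = re.sub(r"^\s*ENVI\s*\n", "", text)
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE | re.DOTALL)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        fields[key] = m.group(2).strip()
    return fields


def _parse_brace_list(raw: str) -> list[str]:
    return [tok.strip() for tok in raw.strip("{}").split(",") if tok.strip()]


def _normalize_wavelengths(values: np.ndarray) -> np.ndarray:
    """Values below 100 are treated as micrometres and converted to nm."""
    values = np.asarray(values, dtype=float)
    if np.all(values < 100):
        warnings.warn(
            "wavelengths < 100: assuming micrometres and converting to nm",
            stacklevel=3,
        )
        values = values * 1000.0
    return values


def write_scene(scene: Scene, raster_path: str | Path) -> Path:
    """Write a scene as ENVI BSQ binary plus text header.

    The header records the grid, the CRS label, the nodata sentinel,
    per-band wavelengths (nm) and detector tags, so the result
    round-trips through :func:`read_scene`.
    """
    if scene.sensor.n_bands == 0:
        raise ValueError("cannot write a scene with zero bands")
    raster_path = Path(raster_path)
    rows, cols, nbands = scene.shape
    data = np.ascontiguousarray(np.transpose(scene.values, (2, 0, 1)))  # BSQ
    data.astype(np.float64).tofile(raster_path)

    t = scene.transform
    if t.b != 0 or t.d != 0:
        raise ValueError("only axis-aligned transforms are supported on write")
    wl = ", ".join(f"{b.center_nm:.6f}" for b in scene.sensor.bands)
    det = ", ".join(b.detector for b in scene.sensor.bands)
    names = ", ".join(b.name or f"band_{b.index}" for b in scene.sensor.bands)
    header = (
        "ENVI\n"
        f"description = {{{scene.sensor.name}}}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {nbands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 5\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"data ignore value = {scene.nodata}\n"
        f"map info = {{projection, 1, 1, {t.c}, {t.f}, {t.a}, {-t.e}}}\n"
        f"coordinate system string = {{{scene.crs}}}\n"
        f"pixel size m = {scene.sensor.ground_resolution_m}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
        f"detector = {{{det}}}\n"
        f"band names = {{{names}}}\n"
    )
    raster_path.with_suffix(".hdr").write_text(header)
    return raster_path


def read_scene(
    raster_path: str | Path,
    wavelengths_source: str | Path | Sequence[float] | None = None,
) -> Scene:
    """Read an ENVI-style raster with wavelength metadata.

    Wavelengths come from (in priority order) an explicit sequence, a
    CSV sidecar path ``(band_index, wavelength_nm)``, or the header's
    ``wavelength = {...}`` list.  Values below 100 are assumed to be
    micrometres and converted to nm with a warning.
    """
    raster_path = Path(raster_path)
    hdr_path = raster_path.with_suffix(".hdr")
    if not raster_path.exists() or not hdr_path.exists():
        raise FileNotFoundError(f"raster or header missing for {raster_path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        nbands = int(fields["bands"])
        dtype = _ENVI_DTYPES[int(fields["data type"])]
    except KeyError as exc:
        raise ValueError(f"header {hdr_path} missing required field: {exc}") from exc

    interleave = fields.get("interleave", "bsq").lower()
    raw = np.fromfile(raster_path, dtype=dtype)
    if raw.size != rows * cols * nbands:
        raise ValueError(
            f"raster size mismatch: expected {rows * cols * nbands} values, got {raw.size}"
        )
    if interleave == "bsq":
        values = np.transpose(raw.reshape(nbands, rows, cols), (1, 2, 0))
    elif interleave == "bip":
        values = raw.reshape(rows, cols, nbands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")

    if "map info" not in fields:
        raise ValueError(f"{hdr_path}: no map info (georeference) present")
    map_info = _parse_brace_list(fields["map info"])
    x0, y0, sx, sy = (float(v) for v in map_info[3:7])
    transform = Affine.from_origin(x0, y0, sx, sy)
    crs = fields.get("coordinate system string", "").strip("{}").strip()
    if not crs:
        raise ValueError(f"{hdr_path}: no CRS label present")

    wavelengths = _resolve_wavelengths(wavelengths_source, fields, nbands)
    if wavelengths.size != nbands:
        raise ValueError(
            f"wavelength count {wavelengths.size} does not match band count {nbands}"
        )
    detectors = (
        _parse_brace_list(fields["detector"])
        if "detector" in fields
        else ["MSI"] * nbands
    )
    names = _parse_brace_list(fields["band names"]) if "band names" in fields else [None] * nbands
    res = float(fields.get("pixel size m", sx))
    sensor = SensorModel(
        name=fields.get("description", "scene").strip("{}").strip() or "scene",
        bands=tuple(
            BandDef(i, float(w), det, nm)
            for i, (w, det, nm) in enumerate(zip(wavelengths, detectors, names))
        ),
        ground_resolution_m=res,
    )
    nodata = float(fields.get("data ignore value", -9999.0))
    return Scene(values=values, transform=transform, crs=crs, sensor=sensor, nodata=nodata)


def _resolve_wavelengths(source, fields: dict, nbands: int) -> np.ndarray:
    if source is None:
        if "wavelength" not in fields:
            raise ValueError("no wavelength source: header lacks a wavelength list")
        vals = np.array([float(v) for v in _parse_brace_list(fields["wavelength"])])
    elif isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            reader = csv.reader(fh)
            pairs = []
            for row in reader:
                if not row or not row[0].strip() or row[0].strip().lstrip("-").startswith("band"):
                    continue
                pairs.append((int(row[0]), float(row[1])))
        pairs.sort()
        vals = np.array([w for _, w in pairs])
    else:
        vals = np.asarray(list(source), dtype=float)
    return _normalize_wavelengths(vals)


def write_wavelength_sidecar(sensor: SensorModel, path: str | Path) -> Path:
    """Two-column CSV (band_index, wavelength_nm)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["band_index", "wavelength_nm"])
        for b in sensor.bands:
            writer.writerow([b.index, f"{b.center_nm:.6f}"])
    return path


# ---------------------------------------------------------------------------
# Region I/O (GeoJSON)


def read_regions(path: str | Path) -> list[ClassRegion]:
    """Read class-labeled polygons from a GeoJSON feature collection."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    regions = []
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        if "class_code" not in props:
            raise ValueError(f"{path}: feature {k} lacks a class_code property")
        regions.append(
            ClassRegion(
                geometry=shape(feat["geometry"]),
                class_code=str(props["class_code"]),
                region_id=str(props.get("region_id", k)),
            )
        )
    return regions


def write_regions(regions: Iterable[ClassRegion], path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(r.geometry),
                "properties": {"class_code": r.class_code, "region_id": r.region_id},
            }
            for r in regions
        ],
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


# ---------------------------------------------------------------------------
# Band bookkeeping and resampling


def drop_overlap_bands(
    sensor: SensorModel,
    overlap_tolerance_nm: float = DEFAULT_OVERLAP_TOLERANCE_NM,
) -> SensorModel:
    """Remove the SWIR member of each VNIR/SWIR wavelength-coincident pair.

    Two bands coincide when their centers differ by at most
    ``overlap_tolerance_nm``.  All other bands are kept in order, so the
    operation is the identity on sensors without coincident pairs and is
    idempotent.
    """
    vnir_centers = np.array([b.center_nm for b in sensor.bands if b.detector == "VNIR"])
    keep = []
    for i, band in enumerate(sensor.bands):
        if (
            band.detector == "SWIR"
            and vnir_centers.size
            and np.min(np.abs(vnir_centers - band.center_nm)) <= overlap_tolerance_nm
        ):
            continue
        keep.append(i)
    return sensor.subset(keep)


def apply_band_subset(scene: Scene, sensor_after: SensorModel) -> Scene:
    """Slice a scene's cube to the bands of a reduced sensor model.

    Bands are matched by (detector, center wavelength).
    """
    lookup = {(b.detector, round(b.center_nm, 6)): b.index for b in scene.sensor.bands}
    try:
        cols = [lookup[(b.detector, round(b.center_nm, 6))] for b in sensor_after.bands]
    except KeyError as exc:
        raise ValueError(f"band {exc} not present in the scene's sensor") from exc
    return Scene(
        values=scene.values[:, :, cols],
        transform=scene.transform,
        crs=scene.crs,
        sensor=sensor_after,
        nodata=scene.nodata,
    )


def resample_nearest(scene: Scene, target: GridDefinition) -> Scene:
    """Nearest-neighbor resampling onto a target grid in the same CRS.

    Each output pixel takes the value of the input pixel whose center is
    nearest the output pixel center; exact ties break toward the smaller
    row, then the smaller column index.  Output centers falling outside
    the input extent are an error (grids must overlap fully).
    """
    if scene.crs != target.crs:
        raise ValueError(f"CRS mismatch: scene {scene.crs!r} vs target {target.crs!r}")
    xs, ys = target.transform.pixel_centers(target.rows, target.cols)
    inv = scene.transform.invert()
    fcol = inv.a * xs + inv.b * ys + inv.c
    frow = inv.d * xs + inv.e * ys + inv.f
    # fractional pixel index of the nearest input center; the center of
    # input pixel k sits at fractional coordinate k + 0.5, and ceil(f - 0.5)
    # of the half-integer tie point k + 0.5 resolves to k (the smaller index)
    col_idx = np.ceil(fcol - 1.0).astype(int)
    row_idx = np.ceil(frow - 1.0).astype(int)
    rows_in, cols_in, _ = scene.shape
    inside = (
        (row_idx >= 0) & (row_idx < rows_in) & (col_idx >= 0) & (col_idx < cols_in)
    )
    if not inside.any():
        raise ValueError("grids do not overlap")
    if not inside.all():
        raise ValueError(
            f"{int(np.sum(~inside))} target pixel centers fall outside the source extent"
        )
    values = scene.values[row_idx, col_idx, :]
    return Scene(
        values=values,
        transform=target.transform,
        crs=target.crs,
        sensor=scene.sensor,
        nodata=scene.nodata,
    )
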