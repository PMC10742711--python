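"""Spatial data model and I/O.

Observation windows (planar polygons), marked point patterns, categorical
rasters with a NODATA mask, and area partitions (random Voronoi, covariate
quantiles, raster classes, user polygons).  All coordinates are planar /
projected (e.g. UTM metres); distances are Euclidean.

Conventions
-----------
* Raster row 0 is the *southernmost* row; the centroid of cell ``(r, c)`` is
  ``(x0 + (c + 0.5) * xstep, y0 + (r + 0.5) * ystep)``.
* Cells are half-open ``[x_lo, x_hi) x [y_lo, y_hi)``: a point on a shared
  edge belongs to the cell with the larger index.  Points on the outermost
  east/north edge are clamped into the last cell so no observation is lost.
* Point-in-polygon tests count the boundary as inside.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon, shape
from shapely.ops import voronoi_diagram

from .errors import (
    ContainmentError,
    CoverageError,
    GeometryError,
    ParameterError,
    ParseError,
)

__all__ = [
    "ObservationWindow",
    "PointPattern",
    "CategoricalRaster",
    "SubArea",
    "AreaPartition",
    "read_point_pattern",
    "read_window",
    "read_partition_geojson",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_points_csv",
    "window_area",
    "pixellate",
    "sample_points_in_polygon",
    "voronoi_partition",
    "voronoi_partition_from_points",
    "quantile_partition",
    "raster_class_partition",
]

_AREA_RTOL = 1e-6


# ---------------------------------------------------------------------------
# Windows and point patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationWindow:
    """A simple planar polygon bounding the region where events could occur."""

    polygon: Polygon

    def __post_init__(self):
        poly = self.polygon
        if not isinstance(poly, Polygon) or poly.is_empty:
            raise GeometryError("observation window must be a non-empty polygon")
        if not poly.is_valid:
            raise GeometryError("observation window polygon is not simple "
                                "(self-intersecting or otherwise invalid)")
        if poly.area <= 0:
            raise GeometryError("observation window has zero area")

    @classmethod
    def from_vertices(cls, vertices: Sequence[tuple[float, float]]) -> "ObservationWindow":
        return cls(Polygon(vertices))

    @property
    def area(self) -> float:
        """|T|, the shoelace area (positive regardless of orientation)."""
        return float(self.polygon.area)

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax)."""
        xmin, ymin, xmax, ymax = self.polygon.bounds
        return (xmin, xmax, ymin, ymax)

    def covers(self, x, y) -> np.ndarray:
        """Vectorised point-in-window test, boundary counts as inside."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.covers(self.polygon, pts)

    def to_wkt(self) -> str:
        return self.polygon.wkt


def window_area(window: ObservationWindow) -> float:
    """Area |T| of the observation window."""
    return window.area


@dataclass(frozen=True)
class PointPattern:
    """n planar locations inside a window, optionally with categorical marks."""

    coords: np.ndarray  # (n, 2) float
    window: ObservationWindow
    marks: np.ndarray | None = None  # (n,) object/str, or None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "coords", coords)
        if self.marks is not None:
            marks = np.asarray(self.marks, dtype=object).reshape(-1)
            if len(marks) != len(coords):
                raise ParameterError("marks length differs from number of points")
            object.__setattr__(self, "marks", marks)
        if len(coords):
            inside = self.window.covers(coords[:, 0], coords[:, 1])
            if not inside.all():
                k = int((~inside).sum())
                raise ContainmentError(
                    f"{k} point(s) fall outside the observation window")

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def mark_labels(self) -> list:
        """Observed mark labels in first-appearance order."""
        if self.marks is None:
            return []
        seen: dict = {}
        for m in self.marks:
            seen.setdefault(m, None)
        return list(seen)

    def unmarked(self) -> "PointPattern":
        return PointPattern(self.coords, self.window, None)


# ---------------------------------------------------------------------------
# Categorical rasters
# ---------------------------------------------------------------------------


@dataclass
class CategoricalRaster:
    """Gridded values with a NODATA mask and per-axis cell sizes.

    ``values`` may hold categorical labels (ints, strings) or, for covariate
    grids feeding :func:`quantile_partition`, continuous numbers.  Masked
    cells (``mask`` True) are NODATA and are never read by any statistic.
    """

    values: np.ndarray  # (nrows, ncols)
    mask: np.ndarray  # (nrows, ncols) bool, True = NODATA
    origin: tuple[float, float] = (0.0, 0.0)  # lower-left corner
    xstep: float = 1.0
    ystep: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ParameterError("raster values must be a 2-D array")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ParameterError("mask shape differs from values shape")
        if self.xstep <= 0 or self.ystep <= 0:
            raise ParameterError("cell sizes must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area(self) -> float:
        return self.xstep * self.ystep

    @property
    def n_valid(self) -> int:
        return int((~self.mask).sum())

    def valid_values(self) -> np.ndarray:
        """Values of unmasked cells in row-major scan order."""
        return self.values[~self.mask]

    def categories(self) -> list:
        """Distinct valid values in first-appearance (row-major) order."""
        seen: dict = {}
        for v in self.valid_values():
            seen.setdefault(v, None)
        return list(seen)

    def cell_centroid(self, r: int, c: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (c + 0.5) * self.xstep, y0 + (r + 0.5) * self.ystep)

    def valid_centroids(self) -> np.ndarray:
        """(m, 2) centroids of valid cells, row-major order."""
        rr, cc = np.nonzero(~self.mask)
        x0, y0 = self.origin
        return np.column_stack((x0 + (cc + 0.5) * self.xstep,
                                y0 + (rr + 0.5) * self.ystep))

    def cell_index(self, x, y, clamp_edges: bool = True):
        """Half-open cell lookup; returns (row, col) arrays, -1 outside."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        x0, y0 = self.origin
        c = np.floor((x - x0) / self.xstep).astype(int)
        r = np.floor((y - y0) / self.ystep).astype(int)
        if clamp_edges:
            # points exactly on the east/north outer edge belong to the last cell
            c = np.where((c == self.ncols) & np.isclose(x, x0 + self.ncols * self.xstep),
                         self.ncols - 1, c)
            r = np.where((r == self.nrows) & np.isclose(y, y0 + self.nrows * self.ystep),
                         self.nrows - 1, r)
        bad = (c < 0) | (c >= self.ncols) | (r < 0) | (r >= self.nrows)
        return np.where(bad, -1, r), np.where(bad, -1, c)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_window(path: str | Path) -> ObservationWindow:
    """Read an observation window from a WKT or GeoJSON polygon file."""
    text = Path(path).read_text().strip()
    try:
        if text.lstrip().startswith("{"):
            obj = json.loads(text)
            if obj.get("type") == "FeatureCollection":
                feats = obj.get("features", [])
                if len(feats) != 1:
                    raise ParseError("window GeoJSON must contain exactly one feature")
                geom = shape(feats[0]["geometry"])
            elif obj.get("type") == "Feature":
                geom = shape(obj["geometry"])
            else:
                geom = shape(obj)
        else:
            geom = shapely.from_wkt(text)
    except ParseError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise ParseError(f"could not parse window file {path}: {exc}") from exc
    if not isinstance(geom, Polygon):
        raise ParseError(f"window file {path} does not contain a single polygon")
    return ObservationWindow(geom)


def read_point_pattern(points_file: str | Path,
                       window_file: str | Path | ObservationWindow,
                       mark_column: str | None = None,
                       drop_outside: bool = False) -> PointPattern:
    """Read a point pattern from a CSV of coordinates plus a window file.

    The CSV must have a header with ``x`` and ``y`` columns; ``mark_column``
    names an optional categorical column.  Points outside the window raise
    :class:`ContainmentError` unless ``drop_outside`` is set, in which case
    they are removed (the count is recorded on the returned pattern's
    ``dropped`` attribute is not kept; a message is emitted via logging).
    """
    import logging

    window = (window_file if isinstance(window_file, ObservationWindow)
              else read_window(window_file))
    path = Path(points_file)
    xs: list[float] = []
    ys: list[float] = []
    marks: list = []
    try:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                fields = []
            else:
                fields = [f.strip() for f in reader.fieldnames]
            if fields and ("x" not in fields or "y" not in fields):
                raise ParseError(f"{path}: CSV needs 'x' and 'y' columns, got {fields}")
            if mark_column is not None and fields and mark_column not in fields:
                raise ParseError(f"{path}: no column named {mark_column!r}")
            for row in reader:
                row = {k.strip(): v for k, v in row.items() if k is not None}
                xs.append(float(row["x"]))
                ys.append(float(row["y"]))
                if mark_column is not None:
                    marks.append(row[mark_column])
    except (ParseError, ContainmentError):
        raise
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"could not parse points CSV {path}: {exc}") from exc

    coords = np.column_stack((xs, ys)) if xs else np.empty((0, 2))
    mk = np.asarray(marks, dtype=object) if mark_column is not None else None
    if drop_outside and len(coords):
        inside = window.covers(coords[:, 0], coords[:, 1])
        n_out = int((~inside).sum())
        if n_out:
            logging.getLogger(__name__).warning(
                "dropped %d point(s) outside the window", n_out)
        coords = coords[inside]
        if mk is not None:
            mk = mk[inside]
    return PointPattern(coords, window, mk)


def write_points_csv(pattern: PointPattern, path: str | Path,
                     mark_name: str = "mark") -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        if pattern.marks is not None:
            writer.writerow(["x", "y", mark_name])
            for (x, y), m in zip(pattern.coords, pattern.marks):
                writer.writerow([repr(float(x)), repr(float(y)), m])
        else:
            writer.writerow(["x", "y"])
            for x, y in pattern.coords:
                writer.writerow([repr(float(x)), repr(float(y))])


def read_ascii_grid(path: str | Path) -> CategoricalRaster:
    """Read an ESRI ASCII grid.

    Accepts the standard header (``cellsize``) and a rectangular-cell
    dialect where ``cellsize`` is replaced by two lines ``dx`` and ``dy``.
    NODATA cells are masked.  The file stores rows north-to-south; they are
    flipped so that row 0 is the southernmost row.
    """
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "dx", "dy", "nodata_value"}:
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner"):
        if key not in header:
            raise ParseError(f"{path}: ASCII grid header missing {key}")
    if "cellsize" in header:
        xstep = ystep = header["cellsize"]
    elif "dx" in header and "dy" in header:
        xstep, ystep = header["dx"], header["dy"]
    else:
        raise ParseError(f"{path}: header needs 'cellsize' or 'dx'+'dy'")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value")

    tokens: list[str] = []
    for line in lines[data_start:]:
        tokens.extend(line.split())
    if len(tokens) != nrows * ncols:
        raise ParseError(f"{path}: expected {nrows * ncols} values, got {len(tokens)}")
    arr = np.array(tokens)
    try:
        num = arr.astype(float)
        intlike = np.all(num[np.isfinite(num)] == np.round(num[np.isfinite(num)]))
        values = num.astype(int) if intlike else num
    except ValueError:
        values = arr.astype(object)
        num = None
    values = np.asarray(values).reshape(nrows, ncols)
    if nodata is not None and num is not None:
        mask = np.isclose(num.reshape(nrows, ncols), nodata)
    elif nodata is not None:
        mask = values == type(values.flat[0])(nodata)
    else:
        mask = np.zeros((nrows, ncols), bool)
    # file is north-to-south; flip to row 0 = south
    values = values[::-1].copy()
    mask = mask[::-1].copy()
    return CategoricalRaster(values, mask,
                             origin=(header["xllcorner"], header["yllcorner"]),
                             xstep=xstep, ystep=ystep)


def write_ascii_grid(raster: CategoricalRaster, path: str | Path,
                     nodata: float = -9999) -> None:
    """Write an ESRI ASCII grid (dx/dy extension only when cells are rectangular)."""
    out = [f"ncols {raster.ncols}", f"nrows {raster.nrows}",
           f"xllcorner {raster.origin[0]!r}", f"yllcorner {raster.origin[1]!r}"]
    if np.isclose(raster.xstep, raster.ystep):
        out.append(f"cellsize {raster.xstep!r}")
    else:
        out.append(f"dx {raster.xstep!r}")
        out.append(f"dy {raster.ystep!r}")
    out.append(f"NODATA_value {nodata}")
    vals = np.where(raster.mask, nodata, raster.values)
    for row in vals[::-1]:  # north-to-south on disk
        out.append(" ".join(str(v) for v in row))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Pixellation
# ---------------------------------------------------------------------------


def pixellate(pattern: PointPattern, nrows: int, ncols: int) -> CategoricalRaster:
    """Discretise a point pattern into a binary presence/absence raster.

    The grid spans the window's bounding box.  A cell is labelled 1
    ('presence') when at least one point falls in it — multiplicities
    collapse — and 0 otherwise.  Cells whose centroid lies outside the
    window polygon are masked NODATA.
    """
    if nrows < 1 or ncols < 1:
        raise ParameterError("nrows and ncols must be >= 1")
    xmin, xmax, ymin, ymax = pattern.window.bounding_box
    if xmax <= xmin or ymax <= ymin:
        raise GeometryError("degenerate window bounding box")
    xstep = (xmax - xmin) / ncols
    ystep = (ymax - ymin) / nrows
    raster = CategoricalRaster(np.zeros((nrows, ncols), int),
                               np.zeros((nrows, ncols), bool),
                               origin=(xmin, ymin), xstep=xstep, ystep=ystep)
    # mask cells whose centroid is outside the polygon
    cc, rr = np.meshgrid(np.arange(ncols), np.arange(nrows))
    cx = xmin + (cc + 0.5) * xstep
    cy = ymin + (rr + 0.5) * ystep
    inside = pattern.window.covers(cx.ravel(), cy.ravel()).reshape(nrows, ncols)
    raster.mask = ~inside
    if pattern.n:
        r, c = raster.cell_index(pattern.coords[:, 0], pattern.coords[:, 1])
        ok = (r >= 0) & ~raster.mask[np.maximum(r, 0), np.maximum(c, 0)]
        raster.values[r[ok], c[ok]] = 1
    return raster


# ---------------------------------------------------------------------------
# Partitions
# ---------------------------------------------------------------------------


@dataclass
class SubArea:
    """One element of an area partition."""

    id: int
    label: str
    size: float  # T_g, same squared unit as coordinates
    centroid: tuple[float, float]
    polygon: Polygon | None = None  # for polygon-based partitions


@dataclass
class AreaPartition:
    """A division of the window into G disjoint sub-areas.

    Holds enough information to assign every point of a pattern to exactly
    one sub-area: polygons (user / Voronoi), Voronoi generators (nearest-
    generator rule with ties broken by lowest id), or a per-cell class grid
    for raster-derived partitions.
    """

    sub_areas: list[SubArea]
    source: str  # voronoi | covariate_quantile | raster_classes | user
    window: ObservationWindow | None = None
    generators: np.ndarray | None = None  # (G, 2), Voronoi only
    class_raster: CategoricalRaster | None = None  # raster-derived only
    class_grid: np.ndarray | None = None  # (nrows, ncols) int, -1 = NODATA

    def __post_init__(self):
        if not self.sub_areas:
            raise ParameterError("partition needs at least one sub-area")
        for sa in self.sub_areas:
            if sa.size <= 0:
                raise GeometryError(f"sub-area {sa.label!r} has non-positive size")
        if self.window is not None and self.source in {"voronoi", "user"}:
            total = sum(sa.size for sa in self.sub_areas)
            if not np.isclose(total, self.window.area, rtol=_AREA_RTOL):
                raise GeometryError(
                    f"sub-area sizes sum to {total!r}, window area is "
                    f"{self.window.area!r}")

    @property
    def G(self) -> int:
        return len(self.sub_areas)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([sa.size for sa in self.sub_areas])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([sa.centroid for sa in self.sub_areas])

    @property
    def labels(self) -> list[str]:
        return [sa.label for sa in self.sub_areas]

    def assign(self, pattern: PointPattern) -> np.ndarray:
        """Sub-area index per point; raises CoverageError on failure."""
        coords = pattern.coords
        if not len(coords):
            return np.empty(0, int)
        if self.generators is not None:
            # nearest generator; np.argmin breaks ties by lowest id
            d2 = ((coords[:, None, :] - self.generators[None, :, :]) ** 2).sum(-1)
            return d2.argmin(axis=1)
        if self.class_grid is not None:
            rast = self.class_raster
            r, c = rast.cell_index(coords[:, 0], coords[:, 1])
            out = np.full(len(coords), -1, int)
            ok = r >= 0
            out[ok] = self.class_grid[r[ok], c[ok]]
            if (out < 0).any():
                raise CoverageError(
                    f"{int((out < 0).sum())} point(s) fall outside the "
                    "partition's raster or in NODATA cells")
            return out
        # polygon membership, boundary-inclusive, first (lowest-id) match
        out = np.full(len(coords), -1, int)
        for sa in self.sub_areas:
            if sa.polygon is None:
                raise CoverageError("partition has no assignable geometry")
            pts = shapely.points(coords[:, 0], coords[:, 1])
            hit = shapely.covers(sa.polygon, pts) & (out < 0)
            out[hit] = sa.id
        if (out < 0).any():
            raise CoverageError(
                f"{int((out < 0).sum())} point(s) not covered by any sub-area")
        return out


def sample_points_in_polygon(window: ObservationWindow, n: int,
                             rng: np.random.Generator,
                             min_separation: float = 0.0) -> np.ndarray:
    """Uniform points in the polygon by rejection sampling from the bbox.

    With ``min_separation`` > 0, candidates closer than that to an accepted
    point are resampled (used to avoid degenerate Voronoi generators).
    """
    xmin, xmax, ymin, ymax = window.bounding_box
    pts: list[np.ndarray] = []
    guard = 0
    while len(pts) < n:
        guard += 1
        if guard > 100000 * max(n, 1):
            raise GeometryError("rejection sampling failed; window too thin?")
        cand = np.array([rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)])
        if not window.covers(cand[0], cand[1]):
            continue
        if min_separation > 0 and pts:
            d = np.sqrt(((np.array(pts) - cand) ** 2).sum(1)).min()
            if d < min_separation:
                continue
        pts.append(cand)
    return np.array(pts).reshape(n, 2)


def voronoi_partition_from_points(window: ObservationWindow,
                                  generators: np.ndarray) -> AreaPartition:
    """Voronoi tessellation around given generators, clipped to the window."""
    generators = np.asarray(generators, float).reshape(-1, 2)
    G = len(generators)
    if G < 1:
        raise ParameterError("need at least one generator")
    if G == 1:
        poly = window.polygon
        sa = SubArea(0, "area_1", poly.area, (poly.centroid.x, poly.centroid.y),
                     polygon=poly)
        return AreaPartition([sa], "voronoi", window, generators=generators)
    cells = voronoi_diagram(shapely.multipoints(generators),
                            envelope=window.polygon)
    # match each raw cell back to its generator
    polys: list[Polygon | None] = [None] * G
    tree = cKDTree(generators)
    for raw in cells.geoms:
        rep = raw.representative_point()
        _, gid = tree.query([rep.x, rep.y])
        clipped = raw.intersection(window.polygon)
        if polys[gid] is None or clipped.area > polys[gid].area:
            polys[gid] = clipped
    subs = []
    for gid, poly in enumerate(polys):
        if poly is None or poly.is_empty or poly.area <= 0:
            raise GeometryError(f"Voronoi cell of generator {gid} is empty "
                                "(generators too close or outside window)")
        subs.append(SubArea(gid, f"area_{gid + 1}", poly.area,
                            (poly.centroid.x, poly.centroid.y), polygon=poly))
    return AreaPartition(subs, "voronoi", window, generators=generators)


def voronoi_partition(window: ObservationWindow, G: int,
                      seed: int | np.random.Generator) -> AreaPartition:
    """Random Voronoi partition: G uniform generators, cells clipped to the window.

    Deterministic given (window, G, seed).  Generators closer than a
    degeneracy tolerance (1e-9 of the bbox diagonal) are resampled.
    """
    if G < 1:
        raise ParameterError("G must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = window.bounding_box
    tol = 1e-9 * float(np.hypot(xmax - xmin, ymax - ymin))
    generators = sample_points_in_polygon(window, G, rng, min_separation=tol)
    return voronoi_partition_from_points(window, generators)


def quantile_partition(raster: CategoricalRaster, k: int,
                       covariate: str = "covariate") -> AreaPartition:
    """Partition a continuous covariate raster into k empirical-quantile classes.

    Type-7 (linear interpolation) quantiles; intervals are left-open,
    right-closed, with the lowest closed at the minimum.  NODATA ignored.
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    vals = raster.valid_values().astype(float)
    if vals.size == 0:
        raise GeometryError("raster has no valid cells")
    if len(np.unique(vals)) < k:
        raise ParameterError(
            f"covariate {covariate!r} has fewer than {k} distinct values")
    breaks = np.quantile(vals, np.linspace(0, 1, k + 1))  # type-7 default
    inner = breaks[1:-1]
    # class j: (q_j, q_{j+1}], lowest closed at the minimum
    grid = np.full(raster.values.shape, -1, int)
    valid = ~raster.mask
    grid[valid] = np.searchsorted(inner, raster.values[valid].astype(float),
                                  side="left")
    return _partition_from_class_grid(
        raster, grid, [f"class_{j + 1}" for j in range(k)], "covariate_quantile")


def raster_class_partition(raster: CategoricalRaster) -> AreaPartition:
    """One sub-area per observed raster category (first-appearance order)."""
    cats = raster.categories()
    if not cats:
        raise GeometryError("raster has no valid cells")
    lookup = {c: i for i, c in enumerate(cats)}
    grid = np.full(raster.values.shape, -1, int)
    valid = ~raster.mask
    grid[valid] = np.array([lookup[v] for v in raster.values[valid]])
    return _partition_from_class_grid(raster, grid, [str(c) for c in cats],
                                      "raster_classes")


def _partition_from_class_grid(raster: CategoricalRaster, grid: np.ndarray,
                               labels: list[str], source: str) -> AreaPartition:
    subs = []
    cell_area = raster.cell_area
    kept_labels = []
    remap = np.full(len(labels), -1, int)
    next_id = 0
    for j, label in enumerate(labels):
        rr, cc = np.nonzero(grid == j)
        if rr.size == 0:
            continue  # empty class carries no area
        x0, y0 = raster.origin
        cx = float((x0 + (cc + 0.5) * raster.xstep).mean())
        cy = float((y0 + (rr + 0.5) * raster.ystep).mean())
        subs.append(SubArea(next_id, label, rr.size * cell_area, (cx, cy)))
        remap[j] = next_id
        kept_labels.append(label)
        next_id += 1
    if not subs:
        raise GeometryError("no non-empty classes in raster partition")
    new_grid = np.where(grid >= 0, remap[np.maximum(grid, 0)], -1)
    return AreaPartition(subs, source, window=None, class_raster=raster,
                         class_grid=new_grid)


def read_partition_geojson(path: str | Path,
                           window: ObservationWindow | None = None) -> AreaPartition:
    """Read a partition from a GeoJSON FeatureCollection of polygons.

    Features may carry an ``id`` property used as the sub-area label.
    """
    try:
        obj = json.loads(Path(path).read_text())
        feats = obj["features"]
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"could not parse partition GeoJSON {path}: {exc}") from exc
    subs = []
    for i, feat in enumerate(feats):
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ParseError(f"partition feature {i} is not a polygon")
        label = str(feat.get("properties", {}).get("id", f"area_{i + 1}"))
        subs.append(SubArea(i, label, geom.area,
                            (geom.centroid.x, geom.centroid.y), polygon=geom))
    return AreaPartition(subs, "user", window=window)


def partition_to_geojson(partition: AreaPartition, path: str | Path) -> None:
    feats = []
    for sa in partition.sub_areas:
        if sa.polygon is None:
            raise ParameterError("only polygon-based partitions can be exported")
        feats.append({
            "type": "Feature",
            "properties": {"id": sa.label, "size": sa.size},
            "geometry": json.loads(shapely.to_geojson(sa.polygon)),
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))
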