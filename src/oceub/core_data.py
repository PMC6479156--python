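"""Occurrence ingestion, geographic validation, and the hexagonal analysis grid.

Everything downstream (endemism, richness, composition, prioritization) runs
on a single spatial scaffold: a grid of flat-top hexagonal cells laid out in
geographic coordinates (WGS84 lon/lat), with the across-flats width of each
hexagon equal to ``cell_size_deg`` (default 1 degree).  Occurrence records are
points that are validated, binned into cells, and collapsed into a boolean
cell x species presence matrix.
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
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon, box, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import explain_validity

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

#: default column mapping for occurrence files
DEFAULT_DIALECT: Mapping[str, str] = {
    "species": "species",
    "lon": "lon",
    "lat": "lat",
    "group": "group",
    "valid_taxon": "valid_taxon",
}

VALID_GROUPS = ("angiosperm", "arthropod", "vertebrate", "other")


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or numpy arrays (broadcast).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Occurrence records
# ---------------------------------------------------------------------------

_OCC_COLUMNS = ["species", "lon", "lat", "group", "valid_geo", "valid_taxon"]


@dataclass
class OccurrenceTable:
    """An ordered, immutable-by-convention table of occurrence records.

    The backing frame always carries the columns ``species, lon, lat, group,
    valid_geo, valid_taxon``.  Filtering operations return new tables; record
    order is stable under identical input.
    """

    df: pd.DataFrame
    provenance: str = ""
    parse_report: dict | None = None

    def __post_init__(self):
        missing = [c for c in _OCC_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"occurrence frame missing columns {missing}")
        self.df = self.df[_OCC_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def valid(self) -> pd.DataFrame:
        """Records usable for biodiversity variables (geo- and taxon-valid)."""
        return self.df[self.df.valid_geo & self.df.valid_taxon]

    @property
    def geo_valid(self) -> pd.DataFrame:
        """Records usable for sampling-effort modelling (geo-valid only)."""
        return self.df[self.df.valid_geo]

    def subset(self, mask) -> "OccurrenceTable":
        return OccurrenceTable(self.df[np.asarray(mask)].copy(), provenance=self.provenance)

    def subset_group(self, group: str) -> "OccurrenceTable":
        if group not in set(self.df["group"].dropna().unique()):
            raise ValueError(f"group {group!r} absent from occurrence table")
        return self.subset(self.df["group"] == group)


def read_occurrences(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> OccurrenceTable:
    """Read a CSV/TSV of occurrence records into an :class:`OccurrenceTable`.

    ``dialect`` maps the canonical field names (``species``, ``lon``, ``lat``
    and optionally ``group``, ``valid_taxon``) to the file's column headers.
    Rows with unparseable or out-of-range coordinates are *retained* with
    ``valid_geo=False`` so they still count toward sampling-effort tallies of
    raw collections; the parse report is attached as ``table.parse_report``
    with keys ``n_read`` and ``n_coord_invalid``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if raw.empty:
        raise ValueError(f"{path}: no records (empty file)")
    for key in ("species", "lon", "lat"):
        if d[key] not in raw.columns:
            raise ValueError(f"{path}: required column {d[key]!r} not in header {list(raw.columns)}")

    species = raw[d["species"]].astype(str).str.strip()
    lon = pd.to_numeric(raw[d["lon"]], errors="coerce")
    lat = pd.to_numeric(raw[d["lat"]], errors="coerce")
    in_range = lon.between(-180.0, 180.0) & lat.between(-90.0, 90.0)
    valid_geo = lon.notna() & lat.notna() & in_range

    if d.get("group") in raw.columns:
        group = raw[d["group"]].astype(str).str.strip().str.lower()
        group = group.where(group.isin(VALID_GROUPS), "other")
    else:
        group = pd.Series("other", index=raw.index)
    if d.get("valid_taxon") in raw.columns:
        vt = raw[d["valid_taxon"]].astype(str).str.strip().str.lower()
        valid_taxon = vt.isin(("true", "1", "yes", "t"))
    else:
        valid_taxon = pd.Series(True, index=raw.index)
    valid_taxon = valid_taxon & (species != "")

    df = pd.DataFrame(
        {
            "species": species,
            "lon": lon,
            "lat": lat,
            "group": group,
            "valid_geo": valid_geo,
            "valid_taxon": valid_taxon,
        }
    )
    report = {"n_read": int(len(df)), "n_coord_invalid": int((~valid_geo).sum())}
    logger.info("read %d records from %s (%d with invalid coordinates)", report["n_read"], path, report["n_coord_invalid"])
    return OccurrenceTable(df, provenance=provenance or str(path), parse_report=report)


def write_occurrences(table: OccurrenceTable, path: str | Path) -> None:
    """Write a table back to CSV (canonical headers); round-trip lossless."""
    table.df.to_csv(path, index=False)


def load_boundary(source) -> BaseGeometry:
    """Coerce a boundary specification into a shapely (multi)polygon.

    Accepts a shapely geometry, a ``(xmin, ymin, xmax, ymax)`` bounding box,
    or a path to a GeoJSON file (Feature, FeatureCollection or bare geometry).
    """
    if isinstance(source, BaseGeometry):
        return source
    if isinstance(source, (tuple, list)) and len(source) == 4:
        return box(*source)
    path = Path(source)
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
        geom = geoms[0]
        for g in geoms[1:]:
            geom = geom.union(g)
        return geom
    if gj.get("type") == "Feature":
        return shape(gj["geometry"])
    return shape(gj)


def validate_geography(table: OccurrenceTable, boundary) -> OccurrenceTable:
    """Flag records falling outside the study boundary as ``valid_geo=False``.

    Points exactly on the boundary count as inside (``covers`` semantics).
    Records already invalid stay invalid.
    """
    geom = load_boundary(boundary)
    if not geom.is_valid:
        raise ValueError(f"invalid boundary geometry: {explain_validity(geom)}")
    df = table.df.copy()
    idx = df.index[df.valid_geo]
    inside = np.array(
        [geom.covers(Point(x, y)) for x, y in zip(df.loc[idx, "lon"], df.loc[idx, "lat"])],
        dtype=bool,
    )
    df.loc[idx, "valid_geo"] = inside
    logger.info("geographic validation: %d pass, %d fail", int(inside.sum()), int((~inside).sum()))
    out = OccurrenceTable(df, provenance=table.provenance, parse_report=table.parse_report)
    return out


# ---------------------------------------------------------------------------
# Hexagonal grid
# ---------------------------------------------------------------------------


@dataclass
class HexGrid:
    """A tiling of flat-top hexagons over a lon/lat extent.

    The across-flats width (vertical, flat-to-flat) equals ``cell_size_deg``;
    the circumradius is ``cell_size_deg / sqrt(3)``.  Cell ids are contiguous
    from 0, row-major from the south-west corner.  The outermost ring of cells
    overhangs the requested extent so every interior point of the extent lies
    in exactly one cell.
    """

    extent: tuple[float, float, float, float]
    cell_size_deg: float
    centers: np.ndarray  # (n, 2) lon/lat
    nrows: int
    ncols: int
    _tree: cKDTree = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self._tree is None:
            self._tree = cKDTree(self.centers)

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def circumradius(self) -> float:
        return self.cell_size_deg / math.sqrt(3.0)

    def cell_polygon(self, cell_id: int) -> Polygon:
        cx, cy = self.centers[cell_id]
        s = self.circumradius
        ang = np.radians(np.arange(0, 360, 60))
        return Polygon(np.column_stack([cx + s * np.cos(ang), cy + s * np.sin(ang)]))

    def _contains(self, cell_id, x, y, eps=1e-9) -> bool:
        # analytic point-in-flat-top-hexagon test (boundary inclusive)
        cx, cy = self.centers[cell_id]
        s = self.circumradius
        h = self.cell_size_deg / 2.0
        dx, dy = abs(x - cx), abs(y - cy)
        return dy <= h + eps and (h * dx + (s / 2.0) * dy) <= s * h + eps

    def assign_points(self, lons, lats) -> np.ndarray:
        """Map points to cell ids; -1 for points outside the tiled area.

        Containment is the hexagon's closed interior; a point on a shared
        edge is resolved to the *lowest* adjacent cell id.
        """
        pts = np.column_stack([np.asarray(lons, float), np.asarray(lats, float)])
        k = min(4, self.n_cells)
        dist, idx = self._tree.query(pts, k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        out = np.full(len(pts), -1, dtype=int)
        for i, (x, y) in enumerate(pts):
            cands = idx[i][dist[i] <= dist[i, 0] + 1e-9]
            hits = sorted(int(c) for c in cands if self._contains(c, x, y))
            if hits:
                out[i] = hits[0]
        return out

    def neighbor_pairs(self) -> np.ndarray:
        """(m, 2) array of adjacent cell-id pairs (hex adjacency)."""
        pairs = self._tree.query_pairs(self.cell_size_deg * 1.05, output_type="ndarray")
        return pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "center_lon": self.centers[:, 0],
                "center_lat": self.centers[:, 1],
            }
        )

    def cell_area_km2(self) -> np.ndarray:
        """Approximate area of each hexagon in km^2 (local equirectangular)."""
        w = self.cell_size_deg
        lat = np.radians(self.centers[:, 1])
        kx = 111.19492664455873 * np.cos(lat)  # km per degree lon at cell latitude
        ky = 111.19492664455873
        return (math.sqrt(3.0) / 2.0) * (w * w) * kx * ky / 1.0  # deg^2 -> km^2


def build_hexgrid(extent: Sequence[float], cell_size_deg: float = 1.0) -> HexGrid:
    """Build a flat-top hexagonal grid covering ``extent = (xmin, ymin, xmax, ymax)``."""
    xmin, ymin, xmax, ymax = map(float, extent)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate extent {extent}")
    if cell_size_deg <= 0:
        raise ValueError("cell_size_deg must be positive")
    s = cell_size_deg / math.sqrt(3.0)
    dx = 1.5 * s
    dy = cell_size_deg
    # one extra column/row on each side guarantees full coverage of the extent
    ncols = int(math.ceil((xmax - xmin) / dx)) + 3
    nrows = int(math.ceil((ymax - ymin) / dy)) + 3
    x0 = xmin - dx
    y0 = ymin - dy
    centers = np.empty((nrows * ncols, 2))
    for i in range(nrows):
        for j in range(ncols):
            centers[i * ncols + j, 0] = x0 + j * dx
            centers[i * ncols + j, 1] = y0 + i * dy + (j % 2) * (dy / 2.0)
    return HexGrid(extent=(xmin, ymin, xmax, ymax), cell_size_deg=cell_size_deg, centers=centers, nrows=nrows, ncols=ncols)


# ---------------------------------------------------------------------------
# Surfaces and presence matrices
# ---------------------------------------------------------------------------


@dataclass
class Surface:
    """Per-cell scalar values on a :class:`HexGrid`; NaN marks no-data."""

    grid: HexGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cells,):
            raise ValueError("surface length must equal grid cell count")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        return np.isfinite(self.values)

    @classmethod
    def full(cls, grid: HexGrid, fill=np.nan) -> "Surface":
        return cls(grid, np.full(grid.n_cells, fill, dtype=float))

    @classmethod
    def from_cells(cls, grid: HexGrid, cell_ids, values) -> "Surface":
        s = cls.full(grid)
        s.values[np.asarray(cell_ids, int)] = np.asarray(values, float)
        return s

    def to_frame(self) -> pd.DataFrame:
        f = self.grid.to_frame()
        f["value"] = self.values
        return f


@dataclass
class PresenceMatrix:
    """Boolean cell x species incidence; rows/columns deterministically sorted."""

    data: pd.DataFrame  # index: cell_id (sorted), columns: species (sorted), bool

    def __post_init__(self):
        self.data = self.data.sort_index().sort_index(axis=1).astype(bool)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_species(self) -> int:
        return self.data.shape[1]


def assign_records(table: OccurrenceTable, grid: HexGrid, require_taxon: bool = True) -> pd.DataFrame:
    """Return the valid records with a ``cell_id`` column (out-of-grid dropped)."""
    df = table.valid if require_taxon else table.geo_valid
    if df.empty:
        raise ValueError("empty presence matrix: no valid records")
    cells = grid.assign_points(df["lon"].to_numpy(), df["lat"].to_numpy())
    out = df.copy()
    out["cell_id"] = cells
    n_out = int((cells < 0).sum())
    if n_out:
        logger.info("assign_records: %d records fall outside the grid and are dropped", n_out)
    return out[out["cell_id"] >= 0]


def assign_cells(table: OccurrenceTable, grid: HexGrid) -> PresenceMatrix:
    """Bin valid records into grid cells and collapse to a presence matrix."""
    rec = assign_records(table, grid)
    if rec.empty:
        raise ValueError("empty presence matrix: no records inside the grid")
    inc = pd.crosstab(rec["cell_id"], rec["species"]) > 0
    return PresenceMatrix(inc)
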