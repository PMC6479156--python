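"""Non-phylogenetic biodiversity surfaces: weighted endemism, resampling-based
species richness, geographic interpolation of endemism (GIE), and the
redundancy screen between candidate input variables.

Species richness is the variable most sensitive to uneven collecting effort,
so the naive per-cell species count is replaced by a two-stage resampling
estimate that equalizes the number of records examined in every cell: draw a
fixed number of records with replacement from the cell's record pool, keep a
fixed-size subsample without replacement, count distinct species, and average
over many repetitions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import (
    HexGrid,
    OccurrenceTable,
    PresenceMatrix,
    Surface,
    assign_records,
    haversine_km,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Weighted endemism
# ---------------------------------------------------------------------------


def species_we(presence: PresenceMatrix) -> pd.Series:
    """Per-species weighted-endemism index: 1 / number of occupied cells."""
    occ = presence.data.sum(axis=0)
    return 1.0 / occ.astype(float)


def weighted_endemism(presence: PresenceMatrix, grid: HexGrid) -> Surface:
    """Cell endemicity: sum of the per-species WE index over present species.

    Conservation identity: summed over all cells this equals the number of
    species in the matrix (each species contributes its full weight exactly
    once across its range).
    """
    if presence.n_species == 0:
        raise ValueError("empty presence matrix")
    we = species_we(presence)
    vals = presence.data.to_numpy() @ we.to_numpy()
    return Surface.from_cells(grid, presence.cell_ids, vals)


# ---------------------------------------------------------------------------
# Resampled species richness
# ---------------------------------------------------------------------------


@dataclass
class ResampleConfig:
    """Two-stage richness resampling parameters.

    ``n_per_sample`` records are drawn *with replacement* from each cell
    (bootstrapping equalizes effort and lets sparsely collected cells
    participate), then ``floor(n_per_sample * subsample_fraction)`` of those
    are kept *without replacement* and distinct species are counted.
    """

    n_per_sample: int = 50
    subsample_fraction: float = 0.25
    reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_per_sample < 1:
            raise ValueError("n_per_sample must be >= 1")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def subsample_size(self) -> int:
        return max(1, int(self.n_per_sample * self.subsample_fraction))


def _resample_cell(species_codes: np.ndarray, cfg: ResampleConfig, rng: np.random.Generator) -> float:
    """Mean distinct-species count for one cell's record pool."""
    n, m = cfg.n_per_sample, cfg.subsample_size
    draws = species_codes[rng.integers(0, len(species_codes), size=(cfg.reps, n))]
    # subsample without replacement: keep m random positions per repetition
    keep = np.argsort(rng.random((cfg.reps, n)), axis=1)[:, :m]
    sub = np.take_along_axis(draws, keep, axis=1)
    sub.sort(axis=1)
    distinct = 1 + (np.diff(sub, axis=1) != 0).sum(axis=1)
    return float(distinct.mean())


def richness_resampled(table: OccurrenceTable, grid: HexGrid, cfg: ResampleConfig) -> Surface:
    """Resampling-based species-richness surface (cells without records: no-data).

    Deterministic for a fixed ``cfg.seed``; invariant in distribution to
    duplicating every record of a cell (the with-replacement draw sees the
    same empirical species distribution).
    """
    rec = assign_records(table, grid)
    rec = rec.sort_values(["cell_id", "species"], kind="mergesort")  # order-invariance
    codes = pd.Categorical(rec["species"]).codes.astype(np.int64)
    surf = Surface.full(grid)
    rng = np.random.default_rng(cfg.seed)
    for cell, idx in rec.groupby("cell_id").indices.items():
        surf.values[int(cell)] = _resample_cell(codes[idx], cfg, rng)
    return surf


def richness_naive(presence: PresenceMatrix, grid: HexGrid) -> Surface:
    """Raw per-cell species count (for effort-bias comparisons)."""
    vals = presence.data.sum(axis=1).to_numpy(dtype=float)
    return Surface.from_cells(grid, presence.cell_ids, vals)


# ---------------------------------------------------------------------------
# Areas of endemism: geographic interpolation of endemism (GIE)
# ---------------------------------------------------------------------------

#: upper class edges (km) of the nine range-size classes
GIE_CLASS_EDGES = np.array([50.0, 200.0, 400.0, 600.0, 800.0, 1000.0, 1500.0, 2000.0, 3299.0])


def gie_class(max_dist_km: float) -> int:
    """Range-size class 1..9 from the centroid-to-farthest-point distance.

    Class 1 covers [0, 50] km; class k covers (edge_{k-1}, edge_k].  Distances
    beyond the last edge (3,299 km) are assigned class 9 with a warning.
    """
    d = float(max_dist_km)
    if d < 0:
        raise ValueError("distance must be nonnegative")
    if d > GIE_CLASS_EDGES[-1]:
        warnings.warn(f"range size {d:.0f} km exceeds the largest class edge; assigned class 9")
        return 9
    return int(np.searchsorted(GIE_CLASS_EDGES, d, side="left")) + 1


@dataclass
class SpeciesDispersion:
    """Range summary of one species: centroid, spread, and GIE class."""

    species_id: str
    centroid_lon: float
    centroid_lat: float
    max_dist_km: float
    gie_class: int


def species_dispersion(table: OccurrenceTable) -> list[SpeciesDispersion]:
    """Centroid (arithmetic lon/lat mean) and farthest-point distance per species."""
    df = table.valid
    if df.empty:
        raise ValueError("no valid records")
    out = []
    for sp, g in df.groupby("species", sort=True):
        clon = float(g["lon"].mean())
        clat = float(g["lat"].mean())
        d = haversine_km(clon, clat, g["lon"].to_numpy(), g["lat"].to_numpy())
        dmax = float(np.max(d)) if len(g) > 1 else 0.0
        out.append(SpeciesDispersion(sp, clon, clat, dmax, gie_class(dmax)))
    return out


def gie_consensus(dispersions: list[SpeciesDispersion], grid: HexGrid) -> Surface:
    """Consensus areas-of-endemism surface.

    For each range-size class, an Epanechnikov kernel surface of the class's
    species centroids is computed with kernel radius equal to the class's
    upper edge; class surfaces are summed with weight ``1/edge_k`` so
    narrow-ranged (more endemic) species dominate; the result is min-max
    rescaled to [0, 1].
    """
    if not dispersions:
        raise ValueError("no species dispersions")
    total = np.zeros(grid.n_cells)
    lons = grid.centers[:, 0]
    lats = grid.centers[:, 1]
    # kernel radii below the grid's resolving power would miss every cell
    # center; the radius is floored at one cell width (the class weight keeps
    # the printed edge, so narrow classes still dominate)
    cell_km = grid.cell_size_deg * 111.19492664455873
    for k in range(1, 10):
        members = [d for d in dispersions if d.gie_class == k]
        if not members:
            continue
        h = max(GIE_CLASS_EDGES[k - 1], cell_km)
        dens = np.zeros(grid.n_cells)
        for d in members:
            dist = haversine_km(d.centroid_lon, d.centroid_lat, lons, lats)
            u = dist / h
            dens += np.where(u < 1.0, 1.0 - u * u, 0.0)
        total += dens / h
    lo, hi = float(total.min()), float(total.max())
    if hi > lo:
        total = (total - lo) / (hi - lo)
    return Surface(grid, total)


# ---------------------------------------------------------------------------
# Redundancy screen with spatially corrected degrees of freedom
# ---------------------------------------------------------------------------


def _correlogram_matrix(z: np.ndarray, dist: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Spatial autocorrelation matrix from a binned distance correlogram.

    ``z`` must be standardized.  Off-diagonal entries get the mean product
    ``z_i z_j`` of all pairs in the same distance bin (clipped to [-1, 1]);
    the diagonal is 1.
    """
    n = len(z)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    edges = np.linspace(0.0, float(d.max()) + 1e-9, n_bins + 1)
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    prod = z[iu[0]] * z[iu[1]]
    rho = np.zeros(n_bins)
    for b in range(n_bins):
        m = which == b
        if m.any():
            rho[b] = np.clip(prod[m].mean(), -1.0, 1.0)
    R = np.eye(n)
    R[iu] = rho[which]
    R[(iu[1], iu[0])] = rho[which]
    return R


def correlation_screen(
    surfaces: dict[str, Surface],
    threshold: float = 0.7,
    n_bins: int = 8,
) -> pd.DataFrame:
    """Pairwise Pearson correlations with effective sample sizes corrected
    for spatial autocorrelation (Clifford–Richardson / Dutilleul style).

    Returns one row per pair: ``r``, ``n``, ``n_eff``, ``p`` (two-sided t test
    on ``n_eff - 2`` degrees of freedom) and ``flagged`` (``|r|`` above the
    redundancy threshold, candidates for manual drop).
    """
    from scipy import stats

    names = list(surfaces)
    if len(names) < 2:
        raise ValueError("need at least 2 surfaces")
    grid = surfaces[names[0]].grid
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = surfaces[a], surfaces[b]
            joint = sa.mask & sb.mask
            n = int(joint.sum())
            if n < 3:
                raise ValueError(f"fewer than 3 jointly unmasked cells for {a} vs {b}")
            x = sa.values[joint]
            y = sb.values[joint]
            r = float(np.corrcoef(x, y)[0, 1])
            coords = grid.centers[joint]
            dist = haversine_km(
                coords[:, 0][:, None], coords[:, 1][:, None], coords[None, :, 0], coords[None, :, 1]
            )
            zx = (x - x.mean()) / (x.std() or 1.0)
            zy = (y - y.mean()) / (y.std() or 1.0)
            rx = _correlogram_matrix(zx, dist, n_bins)
            ry = _correlogram_matrix(zy, dist, n_bins)
            n_eff = 1.0 + n * n / float((rx * ry).sum())
            n_eff = float(np.clip(n_eff, 3.0, n))
            t = r * np.sqrt((n_eff - 2.0) / max(1e-12, 1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), df=n_eff - 2.0))
            rows.append(
                {"var_a": a, "var_b": b, "r": r, "n": n, "n_eff": n_eff, "p": p, "flagged": abs(r) > threshold}
            )
    report = pd.DataFrame(rows)
    for _, row in report[report.flagged].iterrows():
        logger.info("redundant pair flagged: %s vs %s (r=%.3f)", row.var_a, row.var_b, row.r)
    return report
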