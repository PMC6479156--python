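"""Shared spatial statistics: ordinary kriging with bootstrap variogram
refits, kernel-density sampling effort, compositional dissimilarity matrices,
non-metric multidimensional scaling, and continuous composition surfaces.

Interpolation emulates the behaviour of empirical Bayesian kriging — which
propagates variogram-parameter uncertainty by refitting on data subsets — as
ordinary kriging whose variogram is refit on bootstrap subsets of the
samples; the per-cell mean over refits is the prediction and the spread over
refits is the parameter-uncertainty estimate.  All planar computations use a
local equirectangular projection (km), adequate at subcontinental extents.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.manifold import smacof

from .core_data import HexGrid, PresenceMatrix, Surface, haversine_km
from .phylo import EdgeTable, branch_incidence

logger = logging.getLogger(__name__)

KM_PER_DEG = 111.19492664455873


def to_km(lons, lats, ref_lat: float) -> np.ndarray:
    """Project lon/lat to planar km coordinates around a reference latitude."""
    x = np.asarray(lons, float) * KM_PER_DEG * math.cos(math.radians(ref_lat))
    y = np.asarray(lats, float) * KM_PER_DEG
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Variogram fitting and ordinary kriging
# ---------------------------------------------------------------------------

_VARIOGRAM_MODELS = ("exponential", "spherical", "gaussian")


@dataclass
class Variogram:
    """Fitted semivariogram model with practical-range parameterization."""

    model: str
    nugget: float
    sill: float
    range_km: float

    def __post_init__(self):
        if self.model not in _VARIOGRAM_MODELS:
            raise ValueError(f"unknown variogram model {self.model!r}")

    def semivariance(self, d) -> np.ndarray:
        d = np.asarray(d, float)
        c = self.sill - self.nugget
        a = self.range_km
        if self.model == "exponential":
            g = c * (1.0 - np.exp(-3.0 * d / a))
        elif self.model == "gaussian":
            g = c * (1.0 - np.exp(-3.0 * (d / a) ** 2))
        else:  # spherical
            u = np.clip(d / a, 0.0, 1.0)
            g = c * (1.5 * u - 0.5 * u**3)
        out = self.nugget + g
        return np.where(d <= 0, 0.0, out)


def fit_variogram(
    pts_km: np.ndarray,
    values: np.ndarray,
    model: str = "exponential",
    n_lags: int = 12,
    fix_nugget: float | None = None,
) -> Variogram:
    """Weighted-least-squares fit of a variogram model to the empirical
    semivariogram (Cressie weights: pair count / model^2)."""
    diff = pts_km[:, None, :] - pts_km[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(len(values), k=1)
    d = dist[iu]
    g = 0.5 * (values[iu[0]] - values[iu[1]]) ** 2
    dmax = float(d.max()) if d.size else 1.0
    edges = np.linspace(0.0, dmax / 2.0 + 1e-9, n_lags + 1)
    lag_d, lag_g, lag_n = [], [], []
    for i in range(n_lags):
        m = (d > edges[i]) & (d <= edges[i + 1])
        if m.any():
            lag_d.append(d[m].mean())
            lag_g.append(g[m].mean())
            lag_n.append(m.sum())
    lag_d, lag_g, lag_n = map(np.asarray, (lag_d, lag_g, lag_n))
    v0 = max(float(np.var(values)), 1e-12)
    r0 = max(dmax / 3.0, 1e-6)

    def resid(p):
        if fix_nugget is None:
            nug, sill, rng_ = p
        else:
            nug = fix_nugget
            sill, rng_ = p
        vg = Variogram(model, nug, max(sill, nug + 1e-12), rng_)
        pred = vg.semivariance(lag_d)
        w = np.sqrt(lag_n) / np.maximum(pred, 1e-12)
        return w * (pred - lag_g)

    if fix_nugget is None:
        x0 = [0.0, v0, r0]
        bounds = ([0.0, 1e-12, 1e-6], [np.inf, np.inf, np.inf])
    else:
        x0 = [v0, r0]
        bounds = ([1e-12, 1e-6], [np.inf, np.inf])
    sol = least_squares(resid, x0, bounds=bounds, max_nfev=200)
    if fix_nugget is None:
        nug, sill, rng_ = sol.x
    else:
        nug = fix_nugget
        sill, rng_ = sol.x
    return Variogram(model, float(nug), float(max(sill, nug + 1e-12)), float(rng_))


@dataclass
class KrigingConfig:
    model: str = "exponential"
    n_lags: int = 12
    n_subsets: int = 20
    subset_fraction: float = 0.75
    nugget: float | None = None  # None: fitted; 0 forces exact interpolation
    seed: int = 0


@dataclass
class KrigeResult:
    mean: Surface
    spread: Surface
    variogram: Variogram  # base (all-samples) fit


def _ok_predict(pts_km, values, targets_km, vg: Variogram) -> np.ndarray:
    """Ordinary-kriging predictions at target locations."""
    n = len(values)
    diff = pts_km[:, None, :] - pts_km[None, :, :]
    G = vg.semivariance(np.sqrt((diff**2).sum(-1)))
    A = np.ones((n + 1, n + 1))
    A[:n, :n] = G
    A[n, n] = 0.0
    dt = np.sqrt(((pts_km[:, None, :] - targets_km[None, :, :]) ** 2).sum(-1))
    B = np.ones((n + 1, dt.shape[1]))
    B[:n] = vg.semivariance(dt)
    try:
        W = np.linalg.solve(A, B)
    except np.linalg.LinAlgError:
        W = np.linalg.lstsq(A, B, rcond=None)[0]
    return values @ W[:n]


def krige(lons, lats, values, grid: HexGrid, cfg: KrigingConfig | None = None) -> KrigeResult:
    """Interpolate located sample values onto all grid-cell centers.

    Duplicate sample locations are jittered (logged) to keep the kriging
    system nonsingular.  With ``cfg.nugget == 0`` the interpolator is exact
    at sample locations.
    """
    cfg = cfg or KrigingConfig()
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    values = np.asarray(values, float)
    if len(values) < 5:
        raise ValueError("kriging requires at least 5 sample points")
    rng = np.random.default_rng(cfg.seed)
    ref_lat = float(np.mean(lats))
    pts = to_km(lons, lats, ref_lat)
    # jitter exact duplicates
    _, inv, counts = np.unique(np.round(pts, 6), axis=0, return_inverse=True, return_counts=True)
    if (counts > 1).any():
        dup = counts[inv] > 1
        logger.warning("krige: %d duplicate sample locations jittered", int(dup.sum()))
        pts = pts + np.where(dup[:, None], rng.normal(0, 1e-3, pts.shape), 0.0)
    targets = to_km(grid.centers[:, 0], grid.centers[:, 1], ref_lat)

    if np.ptp(values) == 0.0:  # constant field: kriging is the identity
        const = Surface(grid, np.full(grid.n_cells, values[0]))
        return KrigeResult(const, Surface(grid, np.zeros(grid.n_cells)),
                           Variogram(cfg.model, 0.0, 1e-12, 1.0))

    base = fit_variogram(pts, values, cfg.model, cfg.n_lags, fix_nugget=cfg.nugget)
    if cfg.n_subsets <= 0:
        pred = _ok_predict(pts, values, targets, base)
        return KrigeResult(Surface(grid, pred), Surface(grid, np.zeros(grid.n_cells)), base)
    preds = []
    n_sub = max(5, int(len(values) * cfg.subset_fraction))
    for _ in range(cfg.n_subsets):
        idx = rng.choice(len(values), size=min(n_sub, len(values)), replace=False)
        try:
            vg = fit_variogram(pts[idx], values[idx], cfg.model, cfg.n_lags, fix_nugget=cfg.nugget)
        except Exception:
            vg = base
        preds.append(_ok_predict(pts, values, targets, vg))
    preds = np.asarray(preds)
    return KrigeResult(Surface(grid, preds.mean(axis=0)), Surface(grid, preds.std(axis=0)), base)


# ---------------------------------------------------------------------------
# Kernel-density sampling effort
# ---------------------------------------------------------------------------


def silverman_spatial_bandwidth(lons, lats) -> float:
    """Spatial variant of Silverman's rule of thumb (km).

    ``0.9 * min(SD, sqrt(1/ln 2) * Dm) * n^(-0.2)`` where SD is the standard
    distance of the points from their mean center and Dm the median distance
    to the mean center.
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    n = len(lons)
    clon, clat = float(lons.mean()), float(lats.mean())
    d = haversine_km(clon, clat, lons, lats)
    sd = float(np.sqrt(np.mean(d**2)))
    dm = float(np.median(d))
    return 0.9 * min(sd, math.sqrt(1.0 / math.log(2.0)) * dm) * n ** (-0.2)


def kernel_density(lons, lats, grid: HexGrid, bandwidth_km: float | None = None) -> Surface:
    """Quartic-kernel density of points, reported as expected point count per
    cell (the surface integrates to ~n over the plane).

    All-coincident points give a zero rule-of-thumb bandwidth; the fallback
    is one cell width (warned).
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    if len(lons) < 1:
        raise ValueError("kernel_density requires at least one point")
    h = bandwidth_km if bandwidth_km is not None else silverman_spatial_bandwidth(lons, lats)
    cell_km = grid.cell_size_deg * KM_PER_DEG
    if not h or h <= 0:
        h = cell_km
        warnings.warn(f"zero bandwidth (coincident points); falling back to one cell width ({h:.0f} km)")
    elif h < cell_km:
        # below the grid's resolving power the cell-center quadrature breaks down
        logger.info("kernel_density: bandwidth %.0f km floored at one cell width (%.0f km)", h, cell_km)
        h = cell_km
    dens = np.zeros(grid.n_cells)
    cx, cy = grid.centers[:, 0], grid.centers[:, 1]
    chunk = max(1, int(2e7 // max(grid.n_cells, 1)))
    for s in range(0, len(lons), chunk):
        d = haversine_km(lons[None, s : s + chunk], lats[None, s : s + chunk], cx[:, None], cy[:, None])
        u2 = (d / h) ** 2
        dens += np.where(u2 < 1.0, (1.0 - u2) ** 2, 0.0).sum(axis=1)
    dens *= 3.0 / (math.pi * h * h)  # quartic kernel normalization (2-D)
    return Surface(grid, dens * grid.cell_area_km2())


# ---------------------------------------------------------------------------
# Beta-diversity dissimilarity matrices
# ---------------------------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    """Symmetric, zero-diagonal pairwise dissimilarities in [0, 1]."""

    labels: np.ndarray  # cell ids
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("dissimilarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("dissimilarity diagonal must be zero")
        if v.min() < -1e-9 or v.max() > 1.0 + 1e-9:
            raise ValueError("dissimilarities must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _included_cells(presence: PresenceMatrix, min_records: int, record_counts: pd.Series | None):
    keep = presence.data.sum(axis=1) > 0
    if record_counts is not None and min_records > 0:
        counts = record_counts.reindex(presence.data.index).fillna(0)
        keep &= counts >= min_records
    dropped = int((~keep).sum())
    if dropped:
        logger.info("beta diversity: %d cells excluded (empty or under-sampled)", dropped)
    return presence.data[keep]


def beta_sorensen(
    presence: PresenceMatrix,
    min_records: int = 0,
    record_counts: pd.Series | None = None,
) -> DissimilarityMatrix:
    """Pairwise Sørensen dissimilarity 1 - 2a/(2a + b + c) between cells."""
    data = _included_cells(presence, min_records, record_counts)
    if data.empty:
        raise ValueError("no cells left for beta diversity")
    M = data.to_numpy().astype(np.int64)
    a = M @ M.T
    r = M.sum(axis=1)
    sim = 2.0 * a / (r[:, None] + r[None, :])
    return DissimilarityMatrix(data.index.to_numpy(), 1.0 - sim)


def beta_phylosor(
    presence: PresenceMatrix,
    tree,
    min_records: int = 0,
    record_counts: pd.Series | None = None,
) -> DissimilarityMatrix:
    """Pairwise PhyloSor dissimilarity (1 - shared branch length / mean PD)."""
    data = _included_cells(presence, min_records, record_counts)
    if data.empty:
        raise ValueError("no cells left for beta diversity")
    et = tree if isinstance(tree, EdgeTable) else EdgeTable.from_tree(tree)
    sub = PresenceMatrix(data)
    occ, _ = branch_incidence(sub, et)  # (edges, cells)
    pd_c = et.lengths @ occ  # (cells,)
    nonzero = pd_c > 0
    if not nonzero.all():
        logger.info("beta_phylosor: %d cells with no tree species excluded", int((~nonzero).sum()))
    occ = occ[:, nonzero]
    pd_c = pd_c[nonzero]
    labels = sub.cell_ids[nonzero]
    shared = (occ * et.lengths[:, None]).T @ occ.astype(float)
    sim = shared / (0.5 * (pd_c[:, None] + pd_c[None, :]))
    return DissimilarityMatrix(labels, 1.0 - sim)


# ---------------------------------------------------------------------------
# Non-metric multidimensional scaling
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    coords: pd.DataFrame  # index: labels; columns: axis_1..axis_k
    stress: float  # Kruskal stress-1 of the best round
    n_rounds_used: int
    seed: int


def nmds(
    d: DissimilarityMatrix,
    ndim: int = 3,
    n_rounds: int = 100,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-7,
) -> Ordination:
    """Best-of-``n_rounds`` non-metric MDS (SMACOF majorization with isotonic
    regression), reporting Kruskal stress-1; coordinates are centered.

    Labels at zero dissimilarity are collapsed to one representative and
    share coordinates.  The per-round seed stream depends only on ``seed``
    and the round index, so the best stress is nonincreasing in ``n_rounds``.
    """
    n = len(d.labels)
    if n < ndim + 2:
        raise ValueError(f"need at least {ndim + 2} labels for {ndim}-D NMDS")
    V = d.values
    off = V[np.triu_indices(n, k=1)]
    if np.all(off == 0):
        raise ValueError("all dissimilarities are zero; ordination is degenerate")
    # collapse duplicate (zero-dissimilarity) labels
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if V[i, j] == 0:
                parent[find(j)] = find(i)
    roots = np.array([find(i) for i in range(n)])
    reps = np.unique(roots)
    Vr = V[np.ix_(reps, reps)]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_rounds)
    best_coords, best_stress = None, np.inf
    for child in children:
        state = int(child.generate_state(1)[0] % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, stress = smacof(
                Vr,
                metric=False,
                n_components=ndim,
                n_init=1,
                max_iter=max_iter,
                eps=eps,
                random_state=state,
                normalized_stress=True,
            )
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    rep_pos = {r: k for k, r in enumerate(reps)}
    full = best_coords[[rep_pos[r] for r in roots]]
    full = full - full.mean(axis=0, keepdims=True)
    frame = pd.DataFrame(full, index=d.labels, columns=[f"axis_{k + 1}" for k in range(ndim)])
    return Ordination(coords=frame, stress=float(best_stress), n_rounds_used=n_rounds, seed=seed)


def composition_surfaces(
    ordination: Ordination, grid: HexGrid, krige_cfg: KrigingConfig | None = None
) -> list[Surface]:
    """Krige each ordination axis from its sampled cells to the whole grid."""
    cells = ordination.coords.index.to_numpy().astype(int)
    lons = grid.centers[cells, 0]
    lats = grid.centers[cells, 1]
    out = []
    for col in ordination.coords.columns:
        res = krige(lons, lats, ordination.coords[col].to_numpy(), grid, krige_cfg)
        out.append(res.mean)
    return out
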