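"""Biogeographic regionalization: unsupervised maximum-likelihood
classification of the composition surfaces into regions of unique biota.

The classifier is a Gaussian mixture fitted by EM over the per-cell vector
of composition values (species axes concatenated with phylogenetic axes);
each cell is assigned its maximum-posterior component.  The number of
regions can be fixed or chosen by BIC over a configurable range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .core_data import HexGrid, Surface

logger = logging.getLogger(__name__)

NO_REGION = 0  # label for no-data cells; real regions are 1..k


@dataclass
class RegionMap:
    """Per-cell region labels (1..k; 0 marks no-data) on a hex grid."""

    grid: HexGrid
    labels: np.ndarray  # int, len == n_cells
    k: int
    means: np.ndarray | None = None  # (k, n_axes) component means
    covariances: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, int)
        if self.labels.shape != (self.grid.n_cells,):
            raise ValueError("label array must cover the grid")

    @property
    def mask(self) -> np.ndarray:
        return self.labels != NO_REGION

    def to_frame(self) -> pd.DataFrame:
        f = self.grid.to_frame()
        f["region"] = self.labels
        return f


def classify_regions(
    surfaces: list[Surface],
    k: int | str = "auto",
    seed: int = 0,
    k_range: tuple[int, int] = (2, 12),
    reg_covar: float = 1e-6,
    majority_filter: bool = False,
) -> RegionMap:
    """Partition the jointly unmasked cells into ``k`` regions.

    ``k="auto"`` selects the component count by BIC over ``k_range``.  Labels
    are canonicalized by descending region size, so identical partitions get
    identical labelings regardless of EM component order.
    """
    if not surfaces:
        raise ValueError("need at least one composition surface")
    grid = surfaces[0].grid
    X = np.column_stack([s.values for s in surfaces])
    joint = np.isfinite(X).all(axis=1)
    n = int(joint.sum())
    if n == 0:
        raise ValueError("no jointly unmasked cells")
    Xj = X[joint]

    def fit(kk: int) -> GaussianMixture:
        return GaussianMixture(
            n_components=kk,
            covariance_type="full",
            reg_covar=reg_covar,
            n_init=5,
            random_state=seed,
        ).fit(Xj)

    if k == "auto":
        lo, hi = k_range
        hi = min(hi, n)
        best, best_bic = None, np.inf
        for kk in range(lo, hi + 1):
            gm = fit(kk)
            bic = gm.bic(Xj)
            if bic < best_bic - 1e-9:
                best, best_bic = gm, bic
        gm = best
        logger.info("classify_regions: BIC selected k=%d", gm.n_components)
    else:
        k = int(k)
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > n:
            raise ValueError(f"k={k} exceeds the {n} unmasked cells")
        gm = fit(k)

    raw = gm.predict(Xj)
    # canonicalize: biggest region gets label 1
    sizes = np.bincount(raw, minlength=gm.n_components)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(gm.n_components, int)
    remap[order] = np.arange(1, gm.n_components + 1)
    labels = np.full(grid.n_cells, NO_REGION, int)
    labels[joint] = remap[raw]
    means = gm.means_[order]
    covs = gm.covariances_[order]

    if majority_filter:
        labels = _majority_filter(grid, labels)
    return RegionMap(grid=grid, labels=labels, k=int(gm.n_components), means=means, covariances=covs)


def _majority_filter(grid: HexGrid, labels: np.ndarray) -> np.ndarray:
    """Single-pass hex-neighborhood majority vote (no-data cells untouched)."""
    out = labels.copy()
    nbrs: dict[int, list[int]] = {}
    for a, b in grid.neighbor_pairs():
        nbrs.setdefault(int(a), []).append(int(b))
        nbrs.setdefault(int(b), []).append(int(a))
    for c in np.nonzero(labels != NO_REGION)[0]:
        votes = [labels[m] for m in nbrs.get(int(c), []) if labels[m] != NO_REGION]
        votes.append(labels[c])
        vals, counts = np.unique(votes, return_counts=True)
        out[c] = int(vals[np.argmax(counts)])
    return out


def region_contiguity_report(region_map: RegionMap) -> pd.DataFrame:
    """Per-region diagnostics: cell count, connected components (hex
    adjacency), and bounding box.  Regions may legitimately be disjoint."""
    grid = region_map.grid
    labels = region_map.labels
    adj: dict[int, list[int]] = {}
    for a, b in grid.neighbor_pairs():
        if labels[a] != NO_REGION and labels[a] == labels[b]:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
    rows = []
    for r in sorted(set(labels[labels != NO_REGION])):
        cells = np.nonzero(labels == r)[0]
        seen: set[int] = set()
        n_comp = 0
        for c in cells:
            if int(c) in seen:
                continue
            n_comp += 1
            stack = [int(c)]
            seen.add(int(c))
            while stack:
                u = stack.pop()
                for v in adj.get(u, []):
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
        ctr = grid.centers[cells]
        rows.append(
            {
                "region": int(r),
                "n_cells": int(len(cells)),
                "n_components": n_comp,
                "lon_min": float(ctr[:, 0].min()),
                "lon_max": float(ctr[:, 0].max()),
                "lat_min": float(ctr[:, 1].min()),
                "lat_max": float(ctr[:, 1].max()),
            }
        )
    return pd.DataFrame(rows)
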