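"""Final categorization: sampling-effort sufficiency, priority classes, and
regional summaries.

A cell's modelled relevance is only trustworthy where the biota has actually
been sampled, so insufficiency always overrides relevance: a poorly sampled
cell is reported as *insufficient information* no matter what the model says
about it.  An optional vegetation-remnant mask is stamped as a sub-flag and
never changes the main category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .core_data import HexGrid, Surface

CATEGORIES = ("high_relevance_sampled", "low_relevance_sampled", "insufficient_information")
VEG_FLAGS = ("remnant", "cleared", "unknown")


def effort_classes(
    effort: Surface,
    quantile: float = 0.5,
    absolute_cutoff: float | None = None,
) -> np.ndarray:
    """Binary sufficiency map from a sampling-effort surface.

    Default rule: a cell is sufficiently sampled iff its effort reaches the
    given quantile of the *positive*-effort distribution; an absolute density
    cutoff can override the quantile rule.  No-data or zero-effort cells are
    always insufficient.  A constant positive surface is all-sufficient
    (warned: the rule cannot discriminate).
    """
    v = effort.values
    pos = v[np.isfinite(v) & (v > 0)]
    if pos.size == 0:
        return np.zeros(effort.grid.n_cells, bool)
    if absolute_cutoff is not None:
        cutoff = float(absolute_cutoff)
    else:
        if np.ptp(pos) == 0:
            warnings.warn("constant positive effort surface; all cells classed sufficient")
            cutoff = float(pos[0])
        else:
            cutoff = float(np.quantile(pos, quantile))
    return np.isfinite(v) & (v > 0) & (v >= cutoff)


@dataclass
class CategoryMap:
    """Per-cell priority category, with an optional vegetation sub-flag."""

    grid: HexGrid
    categories: np.ndarray  # array of strings from CATEGORIES
    vegetation: np.ndarray | None = None  # strings from VEG_FLAGS, only if a mask was given

    def to_frame(self) -> pd.DataFrame:
        f = self.grid.to_frame()
        f["category"] = self.categories
        if self.vegetation is not None:
            f["vegetation"] = self.vegetation
        return f


def categorize(
    relevance: np.ndarray,
    sufficiency: np.ndarray,
    grid: HexGrid,
    vegetation: np.ndarray | None = None,
) -> CategoryMap:
    """Combine the binary relevance and sufficiency maps into final classes.

    Precedence: insufficient sampling overrides relevance.  ``vegetation``
    (True = native remnant) is recorded as a sub-flag only.
    """
    relevance = np.asarray(relevance, bool)
    sufficiency = np.asarray(sufficiency, bool)
    if relevance.shape != (grid.n_cells,) or sufficiency.shape != (grid.n_cells,):
        raise ValueError("relevance/sufficiency maps misaligned with grid")
    cats = np.where(
        ~sufficiency,
        "insufficient_information",
        np.where(relevance, "high_relevance_sampled", "low_relevance_sampled"),
    )
    veg = None
    if vegetation is not None:
        vegetation = np.asarray(vegetation)
        if vegetation.shape != (grid.n_cells,):
            raise ValueError("vegetation mask misaligned with grid")
        if vegetation.dtype == bool:
            veg = np.where(vegetation, "remnant", "cleared")
        else:
            veg = vegetation.astype(str)
    return CategoryMap(grid=grid, categories=cats, vegetation=veg)


def _zone_labels(grid: HexGrid, zones) -> np.ndarray:
    """Per-cell zone names from a polygon mapping or a per-cell label array."""
    if zones is None:
        return np.full(grid.n_cells, "all", dtype=object)
    if isinstance(zones, dict):
        labels = np.full(grid.n_cells, "unzoned", dtype=object)
        for name, geom in zones.items():
            for i, (x, y) in enumerate(grid.centers):
                if labels[i] == "unzoned" and geom.covers(Point(x, y)):
                    labels[i] = name
        return labels
    arr = np.asarray(zones, dtype=object)
    if arr.shape != (grid.n_cells,):
        raise ValueError("zone labels misaligned with grid")
    return arr


def summarize(category_map: CategoryMap, zones=None) -> pd.DataFrame:
    """Per-zone percentage of cells in each category (rows sum to 100%).

    ``zones`` may be a mapping of zone name to polygon, a per-cell label
    array, or None (single global zone).  Cells covered by no zone polygon
    are reported under ``unzoned``.
    """
    labels = _zone_labels(category_map.grid, zones)
    rows = []
    for zone in pd.unique(labels):
        m = labels == zone
        n = int(m.sum())
        row = {"zone": zone, "n_cells": n}
        for cat in CATEGORIES:
            row[f"pct_{cat}"] = 100.0 * float((category_map.categories[m] == cat).sum()) / n
        row["pct_relevant"] = row["pct_high_relevance_sampled"]
        row["pct_insufficient"] = row["pct_insufficient_information"]
        rows.append(row)
    return pd.DataFrame(rows)
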