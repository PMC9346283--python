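"""Hierarchical segmentation of blink maps into clutches and aggregates.

Three tiers, mirroring the nanoscale organisation of nucleosomes:

1. **Denoising** — DBSCAN (ε = 60 nm, min points = 10) flags isolated blinks
   as outliers; every non-noise blink is kept regardless of its DBSCAN label.
2. **Clutches** — complete-linkage hierarchical clustering cut at a maximum
   intracluster distance of 160 nm groups blinks into nucleosome clutches;
   clusters with fewer than 10 blinks are discarded, and clutches whose blink
   density is below 5× the nucleus's global density are filtered out.
   Complete linkage is used because the cut is a *maximum* pairwise distance
   bound: every retained clutch is guaranteed to span ≤ 160 nm.
3. **Aggregates** — clutches whose blinks come within ε = 30 nm of another
   clutch's blinks are chained into chromatin aggregates (DBSCAN over clutch
   units with min points = 1, which degenerates to single-linkage connected
   components at ε and is implemented as such).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .io import BlinkMap
from .morphometrics import structure_boundary

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationParams",
    "Clutch",
    "Aggregate",
    "denoise_blinks",
    "cluster_clutches",
    "filter_clutches",
    "group_aggregates",
    "segment",
]

#: minimum credible structure area: one reconstruction pixel's inscribed disc
MIN_CLUTCH_AREA = np.pi * 16.0**2


@dataclass(frozen=True)
class SegmentationParams:
    """Defaults are the published cut-offs for embryo chromatin dSTORM data."""

    denoise_eps: float = 60.0
    denoise_min_pts: int = 10
    clutch_max_distance: float = 160.0
    clutch_min_blinks: int = 10
    clutch_density_factor: float = 5.0
    aggregate_eps: float = 30.0
    aggregate_min_pts: int = 1

    def __post_init__(self):
        vals = (
            self.denoise_eps,
            self.denoise_min_pts,
            self.clutch_max_distance,
            self.clutch_min_blinks,
            self.clutch_density_factor,
            self.aggregate_eps,
            self.aggregate_min_pts,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all segmentation parameters must be positive")


@dataclass
class Clutch:
    """A nucleosome clutch: ≥ min_blinks blinks spanning ≤ 160 nm."""

    blink_indices: np.ndarray  # indices into the denoised blink array
    xy: np.ndarray
    boundary: Optional[object] = None  # shapely Polygon (None if degenerate)
    area: float = 0.0
    density: float = float("nan")
    centre: np.ndarray = field(default=None)
    radius_estimate: float = float("nan")

    def __post_init__(self):
        self.blink_indices = np.asarray(self.blink_indices, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.centre is None:
            self.centre = self.xy.mean(axis=0)

    @property
    def n_blinks(self) -> int:
        return len(self.blink_indices)

    def compute_geometry(self) -> None:
        """Fit the non-convex boundary and derive area/density/radius."""
        poly, area = structure_boundary(self.xy)
        self.boundary = poly
        self.area = area
        self.density = self.n_blinks / area if area > 0 else float("inf")
        self.radius_estimate = float(np.sqrt(area / np.pi)) if area > 0 else 0.0


@dataclass
class Aggregate:
    """A chromatin aggregate: one or more proximity-chained clutches."""

    clutch_ids: list
    clutches: list
    boundary: Optional[object] = None
    area: float = 0.0
    approx_diameter: float = 0.0
    density: float = float("nan")

    @property
    def blink_count(self) -> int:
        return int(sum(c.n_blinks for c in self.clutches))

    @property
    def xy(self) -> np.ndarray:
        return np.vstack([c.xy for c in self.clutches])

    def compute_geometry(self) -> None:
        poly, area = structure_boundary(self.xy)
        self.boundary = poly
        self.area = area
        self.approx_diameter = 2.0 * float(np.sqrt(area / np.pi)) if area > 0 else 0.0
        self.density = self.blink_count / area if area > 0 else float("inf")


def pairwise_max_distance(xy: np.ndarray) -> float:
    """Exhaustive all-pairs maximum blink distance (structure span check)."""
    xy = np.asarray(xy, dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def denoise_blinks(
    blinks: BlinkMap, eps: float = 60.0, min_pts: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Flag DBSCAN noise points as outliers.

    Returns (kept_indices, outlier_indices) into ``blinks.xy``.  A point is
    core when at least ``min_pts`` points (itself included) lie within ``eps``;
    non-noise points are kept whatever their cluster label.
    """
    if len(blinks) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(blinks.xy).labels_
    kept = np.flatnonzero(labels != -1)
    outliers = np.flatnonzero(labels == -1)
    return kept, outliers


def cluster_clutches(
    xy: np.ndarray, max_distance: float = 160.0, min_blinks: int = 10
) -> list[Clutch]:
    """Complete-linkage clustering of blinks into nucleosome clutches.

    The dendrogram is cut so every cluster's maximum pairwise blink distance
    is ≤ ``max_distance``; clusters smaller than ``min_blinks`` are dropped.
    Clutch geometry (boundary, area, density) is computed on construction.
    Output order is canonical: clutches sorted by their smallest blink index.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < min_blinks:
        return []
    if len(xy) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        Z = linkage(xy, method="complete")
        labels = fcluster(Z, t=max_distance, criterion="distance")
    clutches = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_blinks:
            continue
        c = Clutch(blink_indices=idx, xy=xy[idx])
        c.compute_geometry()
        clutches.append(c)
    clutches.sort(key=lambda c: int(c.blink_indices.min()))
    return clutches


def filter_clutches(
    clutches: list[Clutch], global_density: float, factor: float = 5.0
) -> list[Clutch]:
    """Drop low-density clutches (density < factor × global density, exclusive).

    Clutches with a degenerate boundary (area below one reconstruction pixel's
    inscribed disc) are also dropped, with the reason logged.
    """
    kept = []
    for c in clutches:
        if c.area < MIN_CLUTCH_AREA:
            logger.info(
                "dropping clutch of %d blinks: degenerate area %.1f nm²",
                c.n_blinks,
                c.area,
            )
            continue
        if c.density < factor * global_density:
            continue
        kept.append(c)
    return kept


def _min_interclutch_distances(
    clutches: list[Clutch], cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pairs (i, j) of clutches whose minimum blink-to-blink distance ≤ cutoff.

    KD-tree accelerated; equals the all-pairs minimum by construction because
    sparse_distance_matrix enumerates every blink pair within the cutoff.
    """
    n = len(clutches)
    trees = [cKDTree(c.xy) for c in clutches]
    ii, jj = [], []
    for i in range(n):
        for j in range(i + 1, n):
            # cheap bounding check before the exact sparse query
            gap = np.linalg.norm(clutches[i].centre - clutches[j].centre)
            reach = (
                np.max(np.linalg.norm(clutches[i].xy - clutches[i].centre, axis=1))
                + np.max(np.linalg.norm(clutches[j].xy - clutches[j].centre, axis=1))
            )
            if gap - reach > cutoff:
                continue
            if trees[i].count_neighbors(trees[j], cutoff) > 0:
                ii.append(i)
                jj.append(j)
    return np.asarray(ii, dtype=int), np.asarray(jj, dtype=int)


def group_aggregates(
    clutches: list[Clutch], eps: float = 30.0, min_pts: int = 1
) -> list[Aggregate]:
    """Chain clutches into chromatin aggregates by blink proximity.

    Two clutches share an aggregate iff they are connected through a chain of
    clutch pairs whose minimum blink-to-blink distance is ≤ ``eps``.  With
    ``min_pts = 1`` every clutch belongs to exactly one aggregate (singletons
    allowed); the DBSCAN-over-units formulation reduces to single-linkage
    connected components at ε, which is what is computed.
    """
    if min_pts != 1:
        raise NotImplementedError("aggregate grouping is defined for min_pts=1")
    n = len(clutches)
    if n == 0:
        return []
    ii, jj = _min_interclutch_distances(clutches, eps)
    adj = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    aggregates = []
    for lab in np.unique(comp):
        ids = np.flatnonzero(comp == lab)
        # canonical id: smallest member clutch index
        agg = Aggregate(clutch_ids=list(ids), clutches=[clutches[i] for i in ids])
        agg.compute_geometry()
        aggregates.append(agg)
    aggregates.sort(key=lambda a: min(a.clutch_ids))
    return aggregates


@dataclass
class SegmentationResult:
    """Full three-tier segmentation of one nucleus."""

    denoised_xy: np.ndarray          # non-noise blinks (nucleus-level statistics)
    kept_indices: np.ndarray          # indices of denoised blinks in the input map
    outlier_indices: np.ndarray
    clutches: list                    # density-filtered clutches
    prefilter_clutches: list          # clutches before the density filter
    aggregates: list
    blink_to_clutch: np.ndarray       # per denoised blink: clutch index or -1


def segment(
    blinks: BlinkMap, params: SegmentationParams = SegmentationParams()
) -> SegmentationResult:
    """Run denoise → clutches → density filter → aggregates on one nucleus.

    The nucleus's global density (blinks / ROI area, post-homogenisation)
    feeds the clutch density filter.  Blinks that survive denoising but end
    up in no retained clutch stay available for nucleus-level statistics.
    """
    kept, outliers = denoise_blinks(blinks, params.denoise_eps, params.denoise_min_pts)
    denoised_xy = blinks.xy[kept]
    logger.info("denoise: %d kept, %d outliers", len(kept), len(outliers))

    pre = cluster_clutches(
        denoised_xy, params.clutch_max_distance, params.clutch_min_blinks
    )
    clutches = filter_clutches(
        pre, blinks.global_density, params.clutch_density_factor
    )
    logger.info("clutches: %d found, %d retained after density filter", len(pre), len(clutches))

    aggregates = group_aggregates(clutches, params.aggregate_eps, params.aggregate_min_pts)
    logger.info("aggregates: %d", len(aggregates))

    assign = np.full(len(denoised_xy), -1, dtype=int)
    for ci, c in enumerate(clutches):
        assign[c.blink_indices] = ci
    return SegmentationResult(
        denoised_xy=denoised_xy,
        kept_indices=kept,
        outlier_indices=outliers,
        clutches=clutches,
        prefilter_clutches=pre,
        aggregates=aggregates,
        blink_to_clutch=assign,
    )
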