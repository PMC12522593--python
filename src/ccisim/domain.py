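"""Spatial windows and region partitions.

Two complementary strategies define where simulated cells may live:

* De novo: the unit square is divided into a ``B x B`` pixel grid and grown
  into ``K`` connected regions by a cyclic random walk seeded at border
  pixels.  Used when no spatial reference exists.
* Data driven: the tissue window is estimated from reference cell centers,
  either as a simple bounding shape (rectangle, convex hull, sectioned
  convex hulls) or by a Delaunay-triangulation boundary that follows concave
  tissue outlines.  Each cell center is padded with a small circular buffer
  so boundary cells end up strictly inside the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

WINDOW_METHODS = ("delaunay", "rectangle", "convex", "sectioned_convex")

#: default circular-buffer radius around each cell center, in reference
#: coordinate units
DEFAULT_BUFFER_RADIUS = 0.0005

#: edges longer than mean + DEFAULT_OUTLIER_SD * SD are pruned from the
#: triangulation before the boundary is extracted
DEFAULT_OUTLIER_SD = 3.0


@dataclass(frozen=True)
class RegionPartition:
    """A ``B x B`` grid of pixels labeled 1..K, each label class connected."""

    labels: np.ndarray
    K: int

    @property
    def B(self) -> int:
        return self.labels.shape[0]

    def region_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Region label for unit-square coordinates (vectorized)."""
        B = self.B
        ix = np.clip((np.asarray(x) * B).astype(int), 0, B - 1)
        iy = np.clip((np.asarray(y) * B).astype(int), 0, B - 1)
        return self.labels[ix, iy]

    def pixels(self, region: int) -> np.ndarray:
        """(n, 2) array of pixel indices belonging to ``region``."""
        return np.argwhere(self.labels == region)

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.labels, fmt="%d", delimiter="\t")


@dataclass(frozen=True)
class SpatialWindow:
    """A tissue window: a simple polygon (or several), holes allowed."""

    geometry: shapely.Geometry

    @property
    def area(self) -> float:
        return float(self.geometry.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.geometry.bounds

    def contains(self, x, y) -> np.ndarray:
        """Closed-set containment test for point(s)."""
        return shapely.intersects(self.geometry, shapely.points(np.asarray(x), np.asarray(y)))

    def contains_strict(self, x, y) -> np.ndarray:
        return shapely.contains_xy(self.geometry, np.asarray(x), np.asarray(y))

    def to_wkt(self) -> str:
        return self.geometry.wkt

    @classmethod
    def from_wkt(cls, wkt: str) -> "SpatialWindow":
        return cls(shapely.from_wkt(wkt))


def _border_pixels(B: int) -> np.ndarray:
    """Pixels with fewer than four edge-sharing neighbors (the grid frame)."""
    idx = []
    for i in range(B):
        for j in range(B):
            if i in (0, B - 1) or j in (0, B - 1):
                idx.append((i, j))
    return np.array(idx)


_NEIGH = ((1, 0), (-1, 0), (0, 1), (0, -1))


def partition_unit_square(K: int, B: int = 20, seed: int | None = None) -> RegionPartition:
    """Partition the unit square grid into K connected regions by random growth.

    Starting from K distinct border pixels, regions grow cyclically: each
    round, every still-active region claims one uniformly chosen unassigned
    edge-sharing neighbor of its current pixel set.  A region stops once all
    of its neighbors are taken; the walk terminates when every pixel is
    labeled.  Because growth is one pixel per region per round, region sizes
    come out similar by construction.
    """
    if B < 2:
        raise ValueError("grid size B must be >= 2")
    border = _border_pixels(B)
    if not 1 <= K <= len(border):
        raise ValueError(f"K={K} must be between 1 and the number of border pixels ({len(border)})")
    rng = np.random.default_rng(seed)
    labels = np.zeros((B, B), dtype=int)
    starts = border[rng.choice(len(border), size=K, replace=False)]
    members: list[list[tuple[int, int]]] = []
    for r, (i, j) in enumerate(starts, start=1):
        labels[i, j] = r
        members.append([(i, j)])
    active = [True] * K
    n_assigned = K
    total = B * B
    while n_assigned < total:
        grew_any = False
        for r in range(K):
            if not active[r]:
                continue
            candidates = set()
            for (i, j) in members[r]:
                for di, dj in _NEIGH:
                    ni, nj = i + di, j + dj
                    if 0 <= ni < B and 0 <= nj < B and labels[ni, nj] == 0:
                        candidates.add((ni, nj))
            if not candidates:
                active[r] = False
                continue
            cand = sorted(candidates)
            pick = cand[rng.integers(len(cand))]
            labels[pick] = r + 1
            members[r].append(pick)
            n_assigned += 1
            grew_any = True
        if not grew_any:  # pragma: no cover - unreachable on a connected grid
            raise RuntimeError("region growth stalled before covering the grid")
    return RegionPartition(labels=labels, K=K)


def _augment_with_buffer(points: np.ndarray, radius: float) -> np.ndarray:
    """Each center plus four buffer points at 0/90/180/270 degrees."""
    offsets = np.array([(radius, 0.0), (0.0, radius), (-radius, 0.0), (0.0, -radius)])
    aug = (points[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    return np.vstack([points, aug])


def _delaunay_window(points: np.ndarray, buffer_radius: float, outlier_sd: float) -> shapely.Geometry:
    aug = _augment_with_buffer(points, buffer_radius)
    tri = Delaunay(aug)
    simplices = tri.simplices
    pts = aug[simplices]  # (n_tri, 3, 2)
    # edge lengths per triangle
    e = np.stack(
        [
            np.linalg.norm(pts[:, 0] - pts[:, 1], axis=1),
            np.linalg.norm(pts[:, 1] - pts[:, 2], axis=1),
            np.linalg.norm(pts[:, 2] - pts[:, 0], axis=1),
        ],
        axis=1,
    )
    # threshold from the unique-edge length distribution
    edges = set()
    for s in simplices:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            edges.add((min(s[a], s[b]), max(s[a], s[b])))
    eidx = np.array(sorted(edges))
    elen = np.linalg.norm(aug[eidx[:, 0]] - aug[eidx[:, 1]], axis=1)
    cutoff = elen.mean() + outlier_sd * elen.std()
    keep = (e <= cutoff).all(axis=1)
    if not keep.any():
        raise ValueError("no triangles survive outlier pruning; raise outlier_sd")
    polys = [Polygon(p) for p in pts[keep]]
    return unary_union(polys)


def estimate_window(
    points: np.ndarray,
    method: str = "delaunay",
    buffer_radius: float = DEFAULT_BUFFER_RADIUS,
    outlier_sd: float = DEFAULT_OUTLIER_SD,
    n_sections: int = 3,
) -> SpatialWindow:
    """Estimate the tissue window holding the given cell centers.

    ``delaunay`` follows concave outlines: centers are padded with four
    buffer points each, a Delaunay triangulation is built on the augmented
    set, triangles with an edge longer than mean + ``outlier_sd`` * SD are
    dropped, and the boundary of the surviving triangles is the window.
    ``rectangle`` and ``convex`` are the usual fast approximations;
    ``sectioned_convex`` unions per-vertical-slice convex hulls (2-5
    sections) as a middle ground for elongated concave tissues.
    """
    points = np.asarray(points, dtype=float)
    if method not in WINDOW_METHODS:
        raise ValueError(f"unknown window method {method!r}; choose from {WINDOW_METHODS}")
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if method == "rectangle":
        if len(points) < 2:
            raise ValueError("rectangle window needs >= 2 points")
        minx, miny = points.min(axis=0)
        maxx, maxy = points.max(axis=0)
        geom = box(minx, miny, maxx, maxy)
    elif method == "convex":
        geom = MultiPoint(points).convex_hull
        if geom.geom_type != "Polygon":
            raise ValueError("points are collinear; convex window is degenerate")
    elif method == "sectioned_convex":
        n_sections = int(np.clip(n_sections, 2, 5))
        xs = points[:, 0]
        cuts = np.linspace(xs.min(), xs.max(), n_sections + 1)
        hulls = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            mask = (xs >= lo) & (xs <= hi)
            if mask.sum() < 3:
                continue
            h = MultiPoint(points[mask]).convex_hull
            if h.geom_type == "Polygon":
                hulls.append(h)
        if not hulls:
            raise ValueError("no section contains 3 non-collinear points")
        geom = unary_union(hulls)
    else:  # delaunay
        if len(points) < 3:
            raise ValueError("delaunay window needs >= 3 points")
        geom = _delaunay_window(points, buffer_radius, outlier_sd)
    if geom.area <= 0:
        raise ValueError("estimated window has zero area (degenerate geometry)")
    return SpatialWindow(geometry=geom)


def estimate_region_windows(
    points: np.ndarray,
    region_labels: np.ndarray,
    method: str = "delaunay",
    buffer_radius: float = DEFAULT_BUFFER_RADIUS,
    outlier_sd: float = DEFAULT_OUTLIER_SD,
    n_sections: int = 3,
    seed: int | None = None,
) -> dict:
    """One window per region; buffer-induced overlaps resolved at random.

    Buffering can make adjacent region windows overlap slightly.  Each
    overlap polygon is assigned wholly to one of its two regions, chosen
    uniformly at random (seeded), so the returned windows have disjoint
    interiors and their union equals the union of the raw windows.
    """
    points = np.asarray(points, dtype=float)
    region_labels = np.asarray(region_labels)
    rng = np.random.default_rng(seed)
    regions = sorted(set(region_labels.tolist()))
    geoms = {}
    for r in regions:
        pts = points[region_labels == r]
        if len(pts) < 3:
            raise ValueError(f"region {r!r} has fewer than 3 points")
        geoms[r] = estimate_window(
            pts, method=method, buffer_radius=buffer_radius,
            outlier_sd=outlier_sd, n_sections=n_sections,
        ).geometry
    for ai in range(len(regions)):
        for bi in range(ai + 1, len(regions)):
            a, b = regions[ai], regions[bi]
            overlap = geoms[a].intersection(geoms[b])
            if overlap.is_empty or overlap.area == 0:
                continue
            if rng.random() < 0.5:
                geoms[b] = geoms[b].difference(overlap)
            else:
                geoms[a] = geoms[a].difference(overlap)
    return {r: SpatialWindow(geometry=g) for r, g in geoms.items()}
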