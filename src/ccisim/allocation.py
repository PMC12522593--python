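"""Cell placement: Poisson point-process fitting and sampling.

For each cell type, the spatial density of reference cells is modeled as an
inhomogeneous Poisson point process with log-polynomial intensity

    log lambda(x, y) = b0 + b1 x + b2 y + b3 x^2 + b4 y^2 + b5 xy
                       [+ b6 x^3 + b7 x^2 y + b8 x y^2 + b9 y^3]

with the cubic terms used only when the type has more than ten cells.  New
coordinates are drawn with a Metropolis-Hastings accept/reject rule: a
proposed location is accepted with probability min(1, lambda(x, y) / c)
where c bounds the intensity from above.  For a Poisson process the accepted
points are independent draws from the normalized intensity, so the sampler
runs the proposal budget as a sequence of accept/reject births.

De novo scenarios skip fitting entirely and place cells uniformly inside
their regions.  A minimum-distance filter mimics the physical impossibility
of overlapping cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.spatial import cKDTree

from ccisim.domain import RegionPartition, SpatialWindow

logger = logging.getLogger(__name__)

DEFAULT_MH_ITERATIONS = 500_000

#: safety margin on the intensity bound c (c must dominate max lambda)
_C_MARGIN = 1.05
_MAX_GRID = 200


def polynomial_terms(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix of monomials in (x, y) up to the given degree (2 or 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cols = [np.ones_like(x), x, y, x**2, y**2, x * y]
    if degree == 3:
        cols += [x**3, x**2 * y, x * y**2, y**3]
    elif degree != 2:
        raise ValueError("degree must be 2 or 3")
    return np.column_stack(cols)


@dataclass
class IntensityModel:
    """Fitted log-polynomial Poisson point-process intensity for one cell type."""

    cell_type: str
    degree: int
    coefficients: np.ndarray
    window: SpatialWindow
    max_log_intensity: float

    def log_intensity(self, x, y) -> np.ndarray:
        X = polynomial_terms(np.asarray(x, float), np.asarray(y, float), self.degree)
        return X @ self.coefficients

    @property
    def log_c(self) -> float:
        """log of the M-H scaling constant c >= max intensity over the window."""
        return self.max_log_intensity + np.log(_C_MARGIN)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cell_type": self.cell_type,
                "degree": self.degree,
                "coefficients": self.coefficients.tolist(),
                "max_log_intensity": self.max_log_intensity,
                "window_wkt": self.window.to_wkt(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "IntensityModel":
        d = json.loads(text)
        return cls(
            cell_type=d["cell_type"],
            degree=d["degree"],
            coefficients=np.asarray(d["coefficients"], float),
            window=SpatialWindow.from_wkt(d["window_wkt"]),
            max_log_intensity=d["max_log_intensity"],
        )


@dataclass
class CellPool:
    """Typed cells with coordinates and region labels."""

    coordinates: np.ndarray  # (n, 2)
    cell_types: np.ndarray  # (n,) str
    regions: np.ndarray  # (n,) labels

    def __len__(self) -> int:
        return len(self.coordinates)

    def subset(self, idx) -> "CellPool":
        return CellPool(self.coordinates[idx], self.cell_types[idx], self.regions[idx])

    @classmethod
    def concat(cls, pools) -> "CellPool":
        pools = list(pools)
        return cls(
            np.vstack([p.coordinates for p in pools]),
            np.concatenate([p.cell_types for p in pools]),
            np.concatenate([p.regions for p in pools]),
        )


def _window_grid(window: SpatialWindow, n: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Regular grid of in-window evaluation points and the per-point area."""
    minx, miny, maxx, maxy = window.bounds
    gx = np.linspace(minx, maxx, n)
    gy = np.linspace(miny, maxy, n)
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    xs, ys = XX.ravel(), YY.ravel()
    inside = window.contains(xs, ys)
    cell_area = (maxx - minx) * (maxy - miny) / (n * n)
    return xs[inside], ys[inside], cell_area


def fit_intensity(
    points: np.ndarray,
    window: SpatialWindow,
    cell_type: str = "",
    degree: int | None = None,
    quadrature_n: int = 32,
) -> IntensityModel:
    """Maximum-likelihood fit of the log-polynomial intensity.

    Uses Berman-Turner quadrature: data points and a regular grid of dummy
    points are pooled, each with an area weight, and the point-process
    likelihood is maximized as a weighted Poisson GLM.  Types with more than
    ten cells get the cubic surface; smaller types the quadratic one, to
    avoid overfitting.  A singular cubic fit falls back to the quadratic.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need at least 2 points to fit an intensity")
    if degree is None:
        degree = 3 if len(points) > 10 else 2
    qx, qy, cell_area = _window_grid(window, quadrature_n)
    x = np.concatenate([points[:, 0], qx])
    y = np.concatenate([points[:, 1], qy])
    is_data = np.concatenate([np.ones(len(points)), np.zeros(len(qx))])
    # Berman-Turner: each quadrature cell's area is split among its points
    minx, miny, maxx, maxy = window.bounds
    nx = quadrature_n
    ix = np.clip(((x - minx) / max(maxx - minx, 1e-300) * nx).astype(int), 0, nx - 1)
    iy = np.clip(((y - miny) / max(maxy - miny, 1e-300) * nx).astype(int), 0, nx - 1)
    cell_id = ix * nx + iy
    counts = np.bincount(cell_id, minlength=nx * nx)
    w = cell_area / counts[cell_id]
    resp = is_data / w

    def _fit(deg: int):
        X = polynomial_terms(x, y, deg)
        model = sm.GLM(resp, X, family=sm.families.Poisson(), var_weights=w)
        return model.fit(maxiter=200)

    try:
        res = _fit(degree)
        if not np.all(np.isfinite(res.params)):
            raise np.linalg.LinAlgError("non-finite coefficients")
    except Exception as exc:
        if degree == 3:
            logger.warning("degree-3 intensity fit failed (%s); falling back to degree 2", exc)
            degree = 2
            res = _fit(2)
        else:
            raise RuntimeError(f"intensity fit failed: {exc}") from exc
    coef = np.asarray(res.params, float)
    ex, ey, _ = _window_grid(window, _MAX_GRID)
    max_log = float(np.max(polynomial_terms(ex, ey, degree) @ coef))
    return IntensityModel(
        cell_type=cell_type,
        degree=degree,
        coefficients=coef,
        window=window,
        max_log_intensity=max_log,
    )


def sample_intensity_mh(
    model: IntensityModel,
    n_target: int,
    iterations: int = DEFAULT_MH_ITERATIONS,
    seed: int | None = None,
    batch: int = 50_000,
) -> np.ndarray:
    """Draw n_target coordinates from the fitted intensity.

    Uniform proposals over the window bounding box are accepted with
    probability min(1, lambda(x, y) / c), c = exp(max log intensity) * 1.05.
    Proposals outside the window are rejected outright.  The accepted set is
    thinned uniformly (acceptance already weighted the draw) or topped up by
    further accept/reject births until exactly n_target points remain.
    """
    if n_target == 0:
        return np.empty((0, 2))
    if n_target < 0:
        raise ValueError("n_target must be >= 0")
    window = model.window
    if window.area <= 0:
        raise ValueError("window has zero area")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = window.bounds
    log_c = model.log_c
    accepted: list[np.ndarray] = []
    n_acc = 0
    proposed = 0
    # keep proposing in vectorized batches; never stop short of n_target
    while proposed < iterations or n_acc < n_target:
        m = min(batch, max(iterations - proposed, batch if n_acc < n_target else 0))
        if m == 0:
            break
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        u = rng.random(m)
        inside = window.contains(xs, ys)
        ok = np.zeros(m, dtype=bool)
        if inside.any():
            ll = model.log_intensity(xs[inside], ys[inside])
            ok[inside] = np.log(u[inside]) < ll - log_c
        accepted.append(np.column_stack([xs[ok], ys[ok]]))
        n_acc += int(ok.sum())
        proposed += m
        if proposed > 200 * iterations:  # pragma: no cover - pathological intensity
            raise RuntimeError("acceptance rate too low to reach n_target")
    pts = np.vstack(accepted)
    if len(pts) > n_target:
        keep = rng.choice(len(pts), size=n_target, replace=False)
        pts = pts[keep]
    return pts


def _uniform_in_window(window: SpatialWindow, n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = window.bounds
    out = []
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        inside = window.contains(xs, ys)
        pts = np.column_stack([xs[inside], ys[inside]])
        out.append(pts)
        got += len(pts)
    return np.vstack(out)[:n]


def _uniform_in_pixels(pixels: np.ndarray, B: int, n: int, rng: np.random.Generator) -> np.ndarray:
    pick = pixels[rng.integers(len(pixels), size=n)]
    offs = rng.random((n, 2))
    return (pick + offs) / B


def allocate_uniform(domain, n_by_type: dict, seed: int | None = None) -> CellPool:
    """Uniform cell placement, for de novo maps with no spatial reference.

    ``domain`` is a RegionPartition, a SpatialWindow, or a mapping of region
    label to SpatialWindow.  ``n_by_type`` is either ``{type: n}`` (single
    region, or placed over the whole partition with regions read off the
    pixel labels) or ``{region: {type: n}}``.
    """
    rng = np.random.default_rng(seed)
    nested = n_by_type and all(isinstance(v, dict) for v in n_by_type.values())
    coords, types, regions = [], [], []

    def _emit(pts, ct, region):
        coords.append(pts)
        types.append(np.full(len(pts), ct, dtype=object))
        regions.append(np.full(len(pts), region, dtype=object))

    if isinstance(domain, RegionPartition):
        if nested:
            for region, table in n_by_type.items():
                pix = domain.pixels(int(region))
                if len(pix) == 0:
                    raise ValueError(f"region {region!r} not present in partition")
                for ct, n in table.items():
                    if n < 0:
                        raise ValueError("cell counts must be >= 0")
                    _emit(_uniform_in_pixels(pix, domain.B, int(n), rng), ct, region)
        else:
            for ct, n in n_by_type.items():
                pts = rng.random((int(n), 2))
                reg = domain.region_of(pts[:, 0], pts[:, 1])
                coords.append(pts)
                types.append(np.full(len(pts), ct, dtype=object))
                regions.append(reg.astype(object))
    elif isinstance(domain, SpatialWindow):
        table = n_by_type if not nested else {ct: n for t in n_by_type.values() for ct, n in t.items()}
        for ct, n in table.items():
            if n < 0:
                raise ValueError("cell counts must be >= 0")
            _emit(_uniform_in_window(domain, int(n), rng), ct, 1)
    elif isinstance(domain, dict):
        if not nested:
            raise ValueError("per-region windows require per-region cell counts")
        for region, table in n_by_type.items():
            window = domain[region]
            for ct, n in table.items():
                _emit(_uniform_in_window(window, int(n), rng), ct, region)
    else:
        raise TypeError(f"unsupported domain type {type(domain)!r}")
    if not coords:
        return CellPool(np.empty((0, 2)), np.empty(0, object), np.empty(0, object))
    return CellPool(np.vstack(coords), np.concatenate(types), np.concatenate(regions))


def remove_overlaps(points: np.ndarray, min_distance: float, seed: int | None = None) -> np.ndarray:
    """Indices of a maximal subset with pairwise distance >= min_distance.

    Points are visited in random order; a point is kept unless a previously
    kept point lies strictly within min_distance, so within each conflict
    cluster the survivor is chosen uniformly at random and every removed
    point has a kept point nearby.  Returns indices into ``points``.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    if n == 0 or min_distance == 0:
        return np.arange(n)
    tree = cKDTree(points)
    pairs = tree.query_pairs(min_distance, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
        pairs = pairs[d < min_distance]  # strict: equality is allowed to stay
    if len(pairs) == 0:
        return np.arange(n)
    neigh: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        neigh[a].append(b)
        neigh[b].append(a)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    kept = np.zeros(n, dtype=bool)
    for i in order:
        if any(kept[j] for j in neigh[i]):
            continue
        kept[i] = True
    return np.flatnonzero(kept)
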