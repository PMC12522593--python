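"""Cell-type colocalization: estimation and simulation.

Estimation mirrors neighbor-enrichment analysis on tissue: build a neighbor
graph (kNN, Delaunay, or distance threshold), count how often two cell types
are adjacent, and compare against the frequency expected under random label
placement (permutation of node labels).  The enrichment score is the log2
ratio of observed to expected neighbor frequency with a permutation p-value.

Simulation plants attraction/inhibition: an inflated pool of candidate cells
is generated, each candidate's selection probability follows a logistic
model whose log-odds accumulate neighborhood-density terms weighted by the
interaction strengths, plus a per-type intercept solved so that the mean
selection probability matches the target/pool ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import Delaunay, cKDTree
from scipy.special import expit

from ccisim.allocation import CellPool

logger = logging.getLogger(__name__)

NEIGHBOR_METHODS = ("knn", "delaunay", "distance")

DEFAULT_N_PERMUTATIONS = 2000
DEFAULT_INFLATION = 1.5

_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class NeighborGraph:
    """Undirected neighbor relation over cells."""

    method: str
    parameter: float
    edges: np.ndarray  # (m, 2) int, each row sorted, no self-edges
    n_nodes: int

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def edge_set(self) -> set:
        return {tuple(e) for e in self.edges.tolist()}


@dataclass(frozen=True)
class ColocalizationEstimate:
    type_pair: tuple
    enrichment: float  # log2 observed/expected neighbor frequency
    p_value: float
    observed: float
    expected: float
    degenerate: bool = False  # pseudo-count rescued a zero expectation


@dataclass(frozen=True)
class ColocalizationSpec:
    """Planted attraction (strength > 0) or inhibition (strength < 0)."""

    type_pair: tuple
    strength: float

    @property
    def same_type(self) -> bool:
        return self.type_pair[0] == self.type_pair[1]


def build_neighbor_graph(
    points: np.ndarray,
    method: str = "knn",
    parameter: float = 6,
    prune_sd: float | None = None,
) -> NeighborGraph:
    """Neighbor graph by kNN (symmetrized), Delaunay, or distance threshold.

    For Delaunay, ``prune_sd`` optionally removes edges longer than
    mean + prune_sd * SD of the edge-length distribution.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    if method == "knn":
        k = int(parameter)
        if k < 1:
            raise ValueError("k must be >= 1")
        if k >= n:
            raise ValueError(f"k={k} must be < number of points ({n})")
        tree = cKDTree(points)
        _, idx = tree.query(points, k=k + 1)
        src = np.repeat(np.arange(n), k)
        dst = idx[:, 1:].ravel()
        pairs = np.sort(np.column_stack([src, dst]), axis=1)
        edges = np.unique(pairs, axis=0)
    elif method == "distance":
        if parameter <= 0:
            raise ValueError("radius must be > 0")
        tree = cKDTree(points)
        edges = tree.query_pairs(float(parameter), output_type="ndarray")
        edges = np.sort(edges, axis=1)
        edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))] if len(edges) else edges.reshape(0, 2)
    elif method == "delaunay":
        tri = Delaunay(points)
        raw = set()
        for s in tri.simplices:
            for a, b in ((0, 1), (1, 2), (2, 0)):
                raw.add((min(s[a], s[b]), max(s[a], s[b])))
        edges = np.array(sorted(raw))
        if prune_sd is not None and len(edges):
            lens = np.linalg.norm(points[edges[:, 0]] - points[edges[:, 1]], axis=1)
            edges = edges[lens <= lens.mean() + prune_sd * lens.std()]
    else:
        raise ValueError(f"unknown neighbor method {method!r}; choose from {NEIGHBOR_METHODS}")
    return NeighborGraph(method=method, parameter=float(parameter), edges=edges.astype(int), n_nodes=n)


def _pair_counts(codes_a: np.ndarray, codes_b: np.ndarray, n_types: int) -> np.ndarray:
    """Count unordered type-pair occurrences over edges; (T, T) upper form."""
    lo = np.minimum(codes_a, codes_b)
    hi = np.maximum(codes_a, codes_b)
    flat = np.bincount(lo * n_types + hi, minlength=n_types * n_types)
    return flat.reshape(n_types, n_types)


def estimate_colocalization(
    graph: NeighborGraph,
    types: np.ndarray,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = None,
) -> list[ColocalizationEstimate]:
    """Permutation enrichment of cell-type adjacency.

    For each unordered type pair, the observed number of adjacent pairs is
    compared to its mean over ``n_perm`` random relabelings of the nodes.
    Enrichment is log2(observed / expected); the two-sided p-value is the
    permutation probability of a deviation from the expectation at least as
    extreme as observed.
    """
    types = np.asarray(types)
    cats, codes = np.unique(types, return_inverse=True)
    T = len(cats)
    if T < 2:
        raise ValueError("need at least 2 cell types present")
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    rng = np.random.default_rng(seed)
    ea, eb = graph.edges[:, 0], graph.edges[:, 1]
    obs = _pair_counts(codes[ea], codes[eb], T)
    perm_counts = np.empty((n_perm, T, T), dtype=float)
    for p in range(n_perm):
        pc = rng.permutation(codes)
        perm_counts[p] = _pair_counts(pc[ea], pc[eb], T)
    expected = perm_counts.mean(axis=0)
    results = []
    for a in range(T):
        for b in range(a, T):
            o, e = float(obs[a, b]), float(expected[a, b])
            degenerate = e == 0.0
            enr = float(np.log2((o + _PSEUDOCOUNT) / (e + _PSEUDOCOUNT)))
            dev = np.abs(perm_counts[:, a, b] - e)
            p_val = float((1 + np.sum(dev >= abs(o - e))) / (n_perm + 1))
            results.append(
                ColocalizationEstimate(
                    type_pair=(cats[a], cats[b]),
                    enrichment=enr,
                    p_value=p_val,
                    observed=o,
                    expected=e,
                    degenerate=degenerate,
                )
            )
            if degenerate:
                logger.warning(
                    "pair (%s, %s) never adjacent in permutations; enrichment uses pseudo-count",
                    cats[a], cats[b],
                )
    return results


def compute_inflation_ratio(
    specs: list[ColocalizationSpec],
    eta: float = DEFAULT_INFLATION,
    nu: float = 0.0,
) -> float:
    """Pool inflation ratio lambda = (sum_j eta * (1 + |a_j|)) ** (1 + nu).

    Stronger interactions and a stronger evenness requirement demand a larger
    candidate pool.  With no interaction specs the sum degenerates; the pool
    then defaults to eta ** (1 + nu).  The ratio is floored at 1 because the
    pool can never be smaller than the target.
    """
    if eta <= 0:
        raise ValueError("inflation parameter eta must be > 0")
    if specs:
        lam = float(sum(eta * (1.0 + abs(s.strength)) for s in specs) ** (1.0 + nu))
    else:
        lam = float(eta ** (1.0 + nu))
    if lam < 1.0:
        warnings.warn(f"inflation ratio {lam:.3f} < 1 clamped to 1 (pool >= target)")
        lam = 1.0
    return lam


def neighborhood_densities(graph: NeighborGraph, types: np.ndarray) -> tuple[dict, np.ndarray]:
    """Per-cell neighborhood densities.

    Returns ``d[t]`` = number of type-t cells among cell i's neighbors, and
    ``d_star`` = neighbor count over its pool-wide mean, the relative local
    crowding used by the evenness term.  Counts (rather than fractions) give
    the interaction strengths enough leverage that planted effects of the
    magnitude estimated from tissue produce visible clustering.
    """
    types = np.asarray(types)
    n = graph.n_nodes
    deg = graph.degrees().astype(float)
    cats = np.unique(types)
    d = {}
    for t in cats:
        cnt = np.zeros(n)
        if graph.n_edges:
            is_t = types == t
            ea, eb = graph.edges[:, 0], graph.edges[:, 1]
            np.add.at(cnt, ea, is_t[eb].astype(float))
            np.add.at(cnt, eb, is_t[ea].astype(float))
        d[t] = cnt
    mean_deg = deg.mean() if deg.mean() > 0 else 1.0
    d_star = deg / mean_deg
    return d, d_star


def _solve_alpha(base_logit: np.ndarray, target_ratio: float, tol: float = 1e-8) -> float:
    """Intercept so that mean sigmoid(base_logit + alpha) == target_ratio.

    The mean of logistic curves is strictly increasing in alpha, so the root
    is unique; bisection via brentq on a wide bracket.
    """

    def f(a):
        return expit(base_logit + a).mean() - target_ratio

    span = float(np.max(np.abs(base_logit))) + 50.0
    lo, hi = -span, span
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError("selection intercept unsolvable (degenerate weights)")
    return brentq(f, lo, hi, xtol=tol)


def select_cells_with_cci(
    pool: CellPool,
    specs: list[ColocalizationSpec],
    targets: dict,
    alpha_star: float = 0.0,
    neighbor_method: str = "knn",
    neighbor_param: float = 6,
    seed: int | None = None,
) -> CellPool:
    """Select target counts per type from an inflated pool under CCI.

    For cell i of type c the selection log-odds are
    mu1 (same-type attraction/inhibition: sum of a_j * d_i,c over same-type
    specs involving c) + mu2 (cross-type terms a*_j * d_i,l) + mu3
    (evenness: local crowding d*_i times alpha_star, negative alpha_star
    thins dense spots) + alpha_c, the per-type intercept solved so the mean
    selection probability equals target_c / pool_c.  Exactly target_c cells
    per type are then drawn without replacement with these weights.

    Types are processed sequentially: each type's neighborhood densities
    are computed on a landscape holding the already-selected cells of
    earlier types and the full candidate pool of later ones, so cross-type
    effects act on cells that will actually be present rather than on pool
    candidates that are about to be discarded.
    """
    rng = np.random.default_rng(seed)
    types = np.asarray(pool.cell_types)
    type_order = list(targets)
    for ct, n_target in targets.items():
        n_pool = int((types == ct).sum())
        if n_pool < n_target:
            raise ValueError(f"pool has {n_pool} cells of type {ct!r} < target {n_target}")
    selected: dict = {}
    outside = np.flatnonzero(~np.isin(types, type_order))
    for ct in type_order:
        n_target = targets[ct]
        cand = np.flatnonzero(types == ct)
        if n_target == 0:
            selected[ct] = np.array([], dtype=int)
            continue
        parts = [cand]
        for t2 in type_order:
            if t2 == ct:
                continue
            parts.append(selected[t2] if t2 in selected else np.flatnonzero(types == t2))
        parts.append(outside)
        land = np.concatenate(parts)
        graph = build_neighbor_graph(
            pool.coordinates[land], method=neighbor_method,
            parameter=min(neighbor_param, len(land) - 1) if neighbor_method == "knn" else neighbor_param,
        )
        d, d_star = neighborhood_densities(graph, types[land])
        zero = np.zeros(len(land))
        logit = np.zeros(len(cand))
        pos = np.arange(len(cand))  # candidates come first in the landscape
        for s in specs:
            a, b = s.type_pair
            if ct not in (a, b):
                continue
            other = a if ct == b else b
            logit += s.strength * d.get(other, zero)[pos]
        logit += alpha_star * d_star[pos]
        ratio = n_target / len(cand)
        alpha_c = _solve_alpha(logit, ratio)
        probs = expit(logit + alpha_c)
        assert abs(probs.mean() - ratio) < 1e-6
        chosen = rng.choice(len(cand), size=n_target, replace=False, p=probs / probs.sum())
        selected[ct] = cand[chosen]
    if not selected:
        return pool.subset(np.array([], dtype=int))
    keep = np.concatenate(list(selected.values()))
    return pool.subset(np.sort(keep))
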