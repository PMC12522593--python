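"""Multi-cell aggregation and fidelity/benchmark metrics.

Spot-level output mimics array-based SRT platforms: the window is cut into
equal squares, each spot's expression is the sum over the cells it contains,
and its coordinate is the square center.  The remaining functions quantify
how well a simulation reproduces a reference (window coverage, bias of
summary statistics, recovery of effect sizes) and score ligand-receptor
predictions against a ground-truth interaction set (balanced accuracy and
permutation-normalized F1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from shapely.geometry import box

from ccisim.domain import SpatialWindow


@dataclass
class SpotGrid:
    """Spot-level (multi-cell) view of a single-cell simulation."""

    n_squares: int
    square_size: float
    spot_centers: np.ndarray  # (n_spots, 2)
    spot_counts: np.ndarray  # genes x spots
    cells_per_spot: np.ndarray


def aggregate_multicell(
    cells_xy: np.ndarray,
    counts: np.ndarray,
    window: SpatialWindow,
    n_squares: int,
) -> SpotGrid:
    """Sum single cells into equal-size square spots tiling the window.

    The window bounding box is tiled with the smallest s x s layout with
    s^2 >= n_squares.  Squares that intersect the window are kept even when
    empty (zero counts); squares wholly outside the tissue are dropped.
    Total counts over spots equal total counts of in-window cells.
    """
    if n_squares < 1:
        raise ValueError("n_squares must be >= 1")
    cells_xy = np.asarray(cells_xy, dtype=float)
    counts = np.asarray(counts)
    s = math.ceil(math.sqrt(n_squares))
    minx, miny, maxx, maxy = window.bounds
    side = max(maxx - minx, maxy - miny) / s
    if side <= 0:
        raise ValueError("window has zero extent")
    inside = window.contains(cells_xy[:, 0], cells_xy[:, 1]) if len(cells_xy) else np.array([], bool)
    ix = np.clip(((cells_xy[:, 0] - minx) / side).astype(int), 0, s - 1)
    iy = np.clip(((cells_xy[:, 1] - miny) / side).astype(int), 0, s - 1)
    square_id = ix * s + iy
    centers, keep_ids = [], []
    for i in range(s):
        for j in range(s):
            sq = box(minx + i * side, miny + j * side, minx + (i + 1) * side, miny + (j + 1) * side)
            if sq.intersects(window.geometry):
                keep_ids.append(i * s + j)
                centers.append((minx + (i + 0.5) * side, miny + (j + 0.5) * side))
    keep_ids = np.array(keep_ids)
    id_to_spot = {int(q): k for k, q in enumerate(keep_ids)}
    G = counts.shape[0]
    spot_counts = np.zeros((G, len(keep_ids)), dtype=counts.dtype)
    cells_per_spot = np.zeros(len(keep_ids), dtype=int)
    for c in np.flatnonzero(inside):
        k = id_to_spot[int(square_id[c])]
        spot_counts[:, k] += counts[:, c]
        cells_per_spot[k] += 1
    return SpotGrid(
        n_squares=n_squares,
        square_size=side,
        spot_centers=np.asarray(centers, dtype=float),
        spot_counts=spot_counts,
        cells_per_spot=cells_per_spot,
    )


def coverage_metrics(sim_window: SpatialWindow, ref_window: SpatialWindow) -> dict:
    """Areal agreement of a simulated window with the reference, in percent.

    total = area(sim)/area(ref); overlap = area(sim & ref)/area(ref);
    ref_only = area(ref - sim)/area(ref); sim_only = area(sim - ref)/area(ref).
    A perfect simulation gives (100, 100, 0, 0).
    """
    ref_area = ref_window.area
    if ref_area <= 0:
        raise ValueError("reference window has zero area")
    sim_g, ref_g = sim_window.geometry, ref_window.geometry
    return {
        "total": 100.0 * sim_g.area / ref_area,
        "overlap": 100.0 * sim_g.intersection(ref_g).area / ref_area,
        "ref_only": 100.0 * ref_g.difference(sim_g).area / ref_area,
        "sim_only": 100.0 * sim_g.difference(ref_g).area / ref_area,
    }


def bias_metrics(sim_values: np.ndarray, ref_values: np.ndarray) -> dict:
    """Absolute bias (sim - ref) and relative bias in percent, with medians.

    Relative bias is NaN (flagged) where the reference value is zero.
    """
    sim = np.asarray(sim_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if sim.shape != ref.shape:
        raise ValueError("sim and ref must have equal length")
    ab = sim - ref
    with np.errstate(divide="ignore", invalid="ignore"):
        rb = np.where(ref != 0, 100.0 * ab / ref, np.nan)
    return {
        "ab": ab,
        "rb_percent": rb,
        "median_ab": float(np.median(ab)),
        "median_rb_percent": float(np.nanmedian(rb)) if np.any(ref != 0) else float("nan"),
        "rb_undefined": int(np.sum(ref == 0)),
    }


def effect_recovery_metrics(sim_effects: np.ndarray, ref_effects: np.ndarray) -> dict:
    """Pearson correlation and MSE between simulated and reference effects."""
    sim = np.asarray(sim_effects, dtype=float)
    ref = np.asarray(ref_effects, dtype=float)
    if sim.shape != ref.shape or sim.size < 3:
        raise ValueError("need equal-length vectors of >= 3 effects")
    if np.all(sim == sim[0]) or np.all(ref == ref[0]):
        raise ValueError("constant effect vector; correlation undefined")
    r, _ = _stats.pearsonr(sim, ref)
    return {"pearson_r": float(r), "mse": float(np.mean((sim - ref) ** 2))}


def _f1(tp: int, fp: int, fn: int) -> float:
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def benchmark_metrics(
    predicted: set,
    truth: set,
    universe: set,
    n_shuffles: int = 100,
    seed: int | None = None,
) -> dict:
    """Score an LR-prediction set against the simulated ground truth.

    Balanced accuracy averages sensitivity and specificity over the
    interaction universe.  The normalized F1 is the observed F1 divided by
    the mean F1 of ``n_shuffles`` size-preserving shuffles of the prediction
    labels over the universe; with zero true positives both the F1 and its
    normalized version are 0 by convention.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty interaction universe")
    predicted = set(predicted)
    truth = set(truth)
    if not predicted <= universe or not truth <= universe:
        raise ValueError("predicted and truth must be subsets of the universe")
    if not truth:
        raise ValueError("empty truth set; sensitivity undefined")
    items = sorted(universe, key=repr)
    y_true = np.array([it in truth for it in items])
    y_pred = np.array([it in predicted for it in items])
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    tpr = tp / (tp + fn)
    tnr = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    balanced = (tpr + tnr) / 2.0
    f1_obs = _f1(tp, fp, fn)
    rng = np.random.default_rng(seed)
    perm_f1 = np.empty(n_shuffles)
    for i in range(n_shuffles):
        yp = rng.permutation(y_pred)
        tp_p = int(np.sum(y_true & yp))
        fp_p = int(np.sum(~y_true & yp))
        fn_p = int(np.sum(y_true & ~yp))
        perm_f1[i] = _f1(tp_p, fp_p, fn_p)
    mean_perm = float(perm_f1.mean())
    if tp == 0:
        norm_f1 = 0.0
    elif mean_perm == 0.0:
        norm_f1 = float("inf") if f1_obs > 0 else 0.0
    else:
        norm_f1 = f1_obs / mean_perm
    return {
        "balanced_accuracy": float(balanced),
        "f1": float(f1_obs),
        "normalized_f1": float(norm_f1),
        "mean_permuted_f1": mean_perm,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }
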