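"""End-to-end simulation: spatial map (stage 1) then expression (stage 2).

The orchestration follows the reference scenario.  With no spatial
reference, the unit square is partitioned into connected regions and cells
are placed uniformly (optionally through the CCI selection model).  With a
paired spatial reference, the window is estimated from the reference
coordinates, per-type Poisson point-process intensities are fitted, and new
coordinates are sampled by accept/reject.  With an unpaired reference the
ancillary spatial table provides the map directly.  Stage 2 fits per-type
ZINB-copula models to the (subsampled) expression reference, draws initial
counts for the simulated cells, and applies all planted CCI and regional
perturbations through the Delta machinery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from ccisim.allocation import (
    CellPool,
    allocate_uniform,
    fit_intensity,
    remove_overlaps,
    sample_intensity_mh,
)
from ccisim.colocalization import (
    build_neighbor_graph,
    compute_inflation_ratio,
    estimate_colocalization,
    select_cells_with_cci,
)
from ccisim.domain import SpatialWindow, estimate_window, partition_unit_square
from ccisim.expression import draw_counts, fit_expression_model, subsample_cells
from ccisim.io import ReferenceBundle, SimulationConfig
from ccisim.metrics import aggregate_multicell
from ccisim.perturbation import accumulate_delta, apply_delta, estimate_gene_pair_cci, estimate_spatial_dependence

logger = logging.getLogger(__name__)


@dataclass
class SimulationResult:
    """One simulated dataset plus the ground truth that generated it."""

    cells: pd.DataFrame
    counts: pd.DataFrame
    ground_truth: dict
    spots: object | None = None  # SpotGrid at multi_cell resolution
    spot_counts: pd.DataFrame | None = None


def _targets_from_reference(reference: ReferenceBundle, config: SimulationConfig) -> dict:
    """Per-region, per-type cell targets; defaults mirror the reference
    composition split evenly across regions."""
    if config.cells_per_region_per_type:
        table = config.cells_per_region_per_type
        nested = all(isinstance(v, dict) for v in table.values())
        if not nested:
            table = {1: dict(table)}
        return {r: {str(t): int(n) for t, n in sub.items()} for r, sub in table.items()}
    by_type = reference.cells["cell_type"].astype(str).value_counts().to_dict()
    K = config.n_regions
    return {r: {t: max(1, n // K) for t, n in by_type.items()} for r in range(1, K + 1)}


def _stage1_de_novo(reference, config, rng) -> pd.DataFrame:
    targets = _targets_from_reference(reference, config)
    window = SpatialWindow(box(0.0, 0.0, 1.0, 1.0))
    if config.n_regions > 1:
        partition = partition_unit_square(config.n_regions, config.grid_size, seed=int(rng.integers(2**31)))
        domain = partition
    else:
        domain = window
    specs = config.planted_colocalization()
    pools = []
    for region, table in targets.items():
        if specs:
            lam = compute_inflation_ratio(specs, eta=config.inflation_eta, nu=config.evenness_nu)
            inflated = {t: math.ceil(lam * n) for t, n in table.items()}
            if isinstance(domain, SpatialWindow):
                pool = allocate_uniform(domain, inflated, seed=int(rng.integers(2**31)))
            else:
                pool = allocate_uniform(domain, {region: inflated}, seed=int(rng.integers(2**31)))
            pool = select_cells_with_cci(
                pool,
                specs,
                table,
                alpha_star=config.evenness_alpha_star,
                neighbor_method=config.neighbor_method,
                neighbor_param=config.neighbor_param,
                seed=int(rng.integers(2**31)),
            )
        else:
            if isinstance(domain, SpatialWindow):
                pool = allocate_uniform(domain, table, seed=int(rng.integers(2**31)))
            else:
                pool = allocate_uniform(domain, {region: table}, seed=int(rng.integers(2**31)))
        pools.append(pool)
    pool = CellPool.concat(pools)
    keep = remove_overlaps(pool.coordinates, config.min_cell_distance, seed=int(rng.integers(2**31)))
    pool = pool.subset(keep)
    return pd.DataFrame(
        {
            "cell_id": [f"sim{i:05d}" for i in range(len(pool))],
            "cell_type": pool.cell_types.astype(str),
            "x": pool.coordinates[:, 0],
            "y": pool.coordinates[:, 1],
            "region": np.asarray(pool.regions).astype(str),
        }
    )


def _stage1_from_spatial(reference, config, rng) -> pd.DataFrame:
    spatial = reference.cells if reference.scenario == "paired" else reference.spatial_cells
    pts = spatial[["x", "y"]].to_numpy(dtype=float)
    window = estimate_window(
        pts,
        method=config.window_method,
        buffer_radius=config.buffer_radius,
    )
    targets = _targets_from_reference(reference, config) if config.cells_per_region_per_type else None
    by_type = spatial["cell_type"].astype(str).value_counts().to_dict()
    if targets is not None:
        flat: dict = {}
        for sub in targets.values():
            for t, n in sub.items():
                flat[t] = flat.get(t, 0) + n
        by_type = flat
    specs = config.planted_colocalization()
    lam = (
        compute_inflation_ratio(specs, eta=config.inflation_eta, nu=config.evenness_nu)
        if specs
        else 1.0
    )
    coords, types = [], []
    for ct, n in by_type.items():
        sub = spatial.loc[spatial["cell_type"].astype(str) == ct, ["x", "y"]].to_numpy(float)
        n_draw = math.ceil(lam * n)
        model = fit_intensity(sub, window, cell_type=ct)
        pts_ct = sample_intensity_mh(
            model, n_draw, iterations=config.mh_iterations, seed=int(rng.integers(2**31))
        )
        coords.append(pts_ct)
        types.append(np.full(len(pts_ct), ct, dtype=object))
    pool = CellPool(
        np.vstack(coords),
        np.concatenate(types),
        np.full(sum(len(c) for c in coords), "1", dtype=object),
    )
    if specs:
        pool = select_cells_with_cci(
            pool,
            specs,
            by_type,
            alpha_star=config.evenness_alpha_star,
            neighbor_method=config.neighbor_method,
            neighbor_param=config.neighbor_param,
            seed=int(rng.integers(2**31)),
        )
    keep = remove_overlaps(pool.coordinates, config.min_cell_distance, seed=int(rng.integers(2**31)))
    pool = pool.subset(keep)
    return pd.DataFrame(
        {
            "cell_id": [f"sim{i:05d}" for i in range(len(pool))],
            "cell_type": pool.cell_types.astype(str),
            "x": pool.coordinates[:, 0],
            "y": pool.coordinates[:, 1],
            "region": np.asarray(pool.regions).astype(str),
        }
    )


def _stage1_inherit_spatial(reference) -> pd.DataFrame:
    spatial = reference.spatial_cells.copy()
    out = pd.DataFrame(
        {
            "cell_id": [f"sim{i:05d}" for i in range(len(spatial))],
            "cell_type": spatial["cell_type"].astype(str).to_numpy(),
            "x": spatial["x"].to_numpy(dtype=float),
            "y": spatial["y"].to_numpy(dtype=float),
        }
    )
    out["region"] = spatial["region"].astype(str).to_numpy() if "region" in spatial else "1"
    return out


def simulate(reference: ReferenceBundle, config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Run both stages and return the simulated dataset with ground truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scenario = config.scenario or reference.scenario
    if scenario == "expression_only":
        cells = _stage1_de_novo(reference, config, rng)
    elif scenario == "paired":
        cells = _stage1_from_spatial(reference, config, rng)
    elif scenario == "unpaired":
        cells = _stage1_inherit_spatial(reference)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    # stage 2: fit reference expression, draw initial counts per cell type
    keep = subsample_cells(
        reference.cells, cap=config.max_cells_per_type_per_region, seed=int(rng.integers(2**31))
    )
    ref_counts = reference.counts.to_numpy()[:, keep]
    ref_types = reference.cells["cell_type"].astype(str).to_numpy()[keep]
    gene_names = reference.gene_names
    models = {}
    for ct in np.unique(ref_types):
        sub = ref_counts[:, ref_types == ct]
        models[ct] = fit_expression_model(
            sub,
            gene_names,
            cell_type=ct,
            use_correlation=config.use_correlation,
            seed=int(rng.integers(2**31)),
        )
    counts = np.zeros((len(gene_names), len(cells)), dtype=np.int64)
    for ct, model in models.items():
        idx = np.flatnonzero(cells["cell_type"].to_numpy() == ct)
        if len(idx) == 0:
            continue
        counts[:, idx] = draw_counts(
            model,
            len(idx),
            depth_factor=config.depth_factor,
            use_correlation=config.use_correlation,
            seed=int(rng.integers(2**31)),
        )
    specs = config.planted_perturbations()
    provenance_summary = []
    if specs:
        delta = accumulate_delta(
            cells, specs, len(gene_names), gene_names=gene_names, seed=int(rng.integers(2**31))
        )
        counts = apply_delta(
            counts, delta, cap_max=config.cap_max_counts, match_depth=config.match_depth
        )
        for rec in delta.provenance:
            provenance_summary.append(
                {
                    "spec_id": rec["spec_id"],
                    "kind": rec["kind"],
                    "n_cells": int(len(rec.get("cells", []))),
                    "genes": np.asarray(rec.get("genes", [])).tolist(),
                    "cells": np.asarray(rec.get("cells", [])).tolist(),
                }
            )
    counts_df = pd.DataFrame(counts, index=gene_names, columns=cells["cell_id"])
    ground_truth = {
        "scenario": scenario,
        "colocalization_specs": config.planted_colocalization(),
        "perturbation_specs": specs,
        "delta_provenance": provenance_summary,
    }
    result = SimulationResult(cells=cells, counts=counts_df, ground_truth=ground_truth)
    if config.output_resolution == "multi_cell":
        xy = cells[["x", "y"]].to_numpy(float)
        minx, miny = xy.min(axis=0)
        maxx, maxy = xy.max(axis=0)
        window = SpatialWindow(box(minx, miny, maxx, maxy))
        grid = aggregate_multicell(xy, counts, window, config.n_squares)
        result.spots = grid
        result.spot_counts = pd.DataFrame(
            grid.spot_counts,
            index=gene_names,
            columns=[f"spot{i:04d}" for i in range(grid.spot_counts.shape[1])],
        )
    return result


def estimate_reference_cci(
    reference: ReferenceBundle,
    config: SimulationConfig,
    lr_pairs: pd.DataFrame | None = None,
    sender_receiver_pairs: list | None = None,
    seed: int | None = None,
) -> dict:
    """Estimate all CCI features from a paired reference.

    Returns colocalization enrichments for all type pairs and, per requested
    (sender, receiver) type pair, the per-gene spatial-dependence effects and
    (if an LR list is given) gene-pair co-expression effects.
    """
    if reference.scenario != "paired":
        raise ValueError("CCI estimation requires a paired spatial-expression reference")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    pts = reference.cells[["x", "y"]].to_numpy(float)
    types = reference.cells["cell_type"].astype(str).to_numpy()
    graph = build_neighbor_graph(pts, method=config.neighbor_method, parameter=config.neighbor_param)
    coloc = estimate_colocalization(
        graph, types, n_perm=config.n_permutations, seed=int(rng.integers(2**31))
    )
    coloc_df = pd.DataFrame(
        {
            "type_a": [c.type_pair[0] for c in coloc],
            "type_b": [c.type_pair[1] for c in coloc],
            "enrichment_log2": [c.enrichment for c in coloc],
            "p_value": [c.p_value for c in coloc],
        }
    )
    out = {"colocalization": coloc_df}
    if sender_receiver_pairs:
        sd_frames, gp_frames = [], []
        counts = reference.counts.to_numpy()
        for sender, receiver in sender_receiver_pairs:
            sd_frames.append(
                estimate_spatial_dependence(
                    counts,
                    reference.cells,
                    graph,
                    sender,
                    receiver,
                    gene_names=reference.gene_names,
                    n_perm=config.n_permutations,
                    seed=int(rng.integers(2**31)),
                )
            )
            if lr_pairs is not None:
                gp_frames.append(
                    estimate_gene_pair_cci(
                        counts,
                        reference.cells,
                        graph,
                        lr_pairs,
                        sender,
                        receiver,
                        gene_names=reference.gene_names,
                        n_perm=config.n_permutations,
                        seed=int(rng.integers(2**31)),
                    )
                )
        out["spatial_dependence"] = pd.concat(sd_frames, ignore_index=True) if sd_frames else None
        if lr_pairs is not None:
            out["gene_pair"] = pd.concat(gp_frames, ignore_index=True) if gp_frames else None
    return out
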