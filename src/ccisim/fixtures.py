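"""Synthetic reference bundles with fully known planted structure.

Every estimator in the package is validated against data whose generating
parameters are known exactly: planted ZINB marginals per gene and cell type,
a planted latent gene-gene correlation, planted colocalization strengths,
and planted expression perturbations.  The generator emulates the three
supported reference shapes -- paired expression + coordinates,
expression-only, and unpaired expression plus a separate spatial table --
at desk scale (default 500 cells x 200 genes, comparable to a small
single-field-of-view imaging dataset).

These bundles are synthetic stand-ins for real tissue references: marginals
are drawn from plausible ranges rather than fitted to any tissue, and no
attempt is made to mimic a particular platform's noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ccisim.allocation import CellPool, allocate_uniform
from ccisim.colocalization import (
    ColocalizationSpec,
    compute_inflation_ratio,
    select_cells_with_cci,
)
from ccisim.domain import SpatialWindow
from ccisim.expression import CellTypeExpressionModel, GeneMarginal, draw_counts
from ccisim.perturbation import PerturbationSpec, accumulate_delta, apply_delta
from shapely.geometry import box

DEFAULT_N_CELLS = 500
DEFAULT_N_GENES = 200


@dataclass
class GroundTruth:
    """Everything needed to recompute what any estimator should recover."""

    cell_types: list
    gene_names: list
    marginals: dict  # cell_type -> list[GeneMarginal]
    sigma: dict  # cell_type -> ndarray | None
    colocalization_specs: list = field(default_factory=list)
    perturbation_specs: list = field(default_factory=list)
    inflation_eta: float = 1.5
    evenness_nu: float = 0.0
    evenness_alpha_star: float = 0.0
    neighbor_method: str = "knn"
    neighbor_param: float = 6
    seed: int | None = None
    delta_provenance: list = field(default_factory=list)  # filled by generate_reference


def _default_truth(
    n_genes: int,
    n_types: int,
    rng: np.random.Generator,
    correlated_pairs: tuple = (),
    colocalization_specs: list | None = None,
    perturbation_specs: list | None = None,
) -> GroundTruth:
    """Plausible single-cell count parameters: log-normal means, moderate
    overdispersion, and zero inflation typical of imaging-based panels."""
    cell_types = [f"type{chr(ord('A') + t)}" for t in range(n_types)]
    gene_names = [f"g{i:04d}" for i in range(n_genes)]
    marginals = {}
    sigma = {}
    for ct in cell_types:
        mu = np.exp(rng.normal(0.8, 0.9, n_genes)).clip(0.2, 60.0)
        disp = rng.uniform(0.8, 4.0, n_genes)
        pi = rng.uniform(0.05, 0.35, n_genes)
        marginals[ct] = [
            GeneMarginal(pi=float(p), mean=float(m), dispersion=float(r))
            for p, m, r in zip(pi, mu, disp)
        ]
        if correlated_pairs:
            S = np.eye(n_genes)
            for a, b, rho in correlated_pairs:
                S[a, b] = S[b, a] = rho
            sigma[ct] = S
        else:
            sigma[ct] = None
    return GroundTruth(
        cell_types=cell_types,
        gene_names=gene_names,
        marginals=marginals,
        sigma=sigma,
        colocalization_specs=list(colocalization_specs or []),
        perturbation_specs=list(perturbation_specs or []),
    )


def _simulate_map(
    truth: GroundTruth,
    targets: dict,
    rng: np.random.Generator,
) -> CellPool:
    window = SpatialWindow(box(0.0, 0.0, 1.0, 1.0))
    if truth.colocalization_specs:
        lam = compute_inflation_ratio(
            truth.colocalization_specs, eta=truth.inflation_eta, nu=truth.evenness_nu
        )
        pool_counts = {ct: math.ceil(lam * n) for ct, n in targets.items()}
        pool = allocate_uniform(window, pool_counts, seed=int(rng.integers(2**31)))
        return select_cells_with_cci(
            pool,
            truth.colocalization_specs,
            targets,
            alpha_star=truth.evenness_alpha_star,
            neighbor_method=truth.neighbor_method,
            neighbor_param=truth.neighbor_param,
            seed=int(rng.integers(2**31)),
        )
    return allocate_uniform(window, targets, seed=int(rng.integers(2**31)))


def generate_reference(
    scenario: str = "paired",
    n_cells: int = DEFAULT_N_CELLS,
    n_genes: int = DEFAULT_N_GENES,
    n_types: int = 3,
    truth: GroundTruth | None = None,
    seed: int | None = 0,
    correlated_pairs: tuple = (),
    colocalization_specs: list | None = None,
    perturbation_specs: list | None = None,
):
    """Generate a reference bundle plus the ground truth that produced it.

    ``truth`` may be supplied to pin every generating parameter; otherwise a
    default truth is drawn (seeded) with the requested planted structure.
    Identical seeds give bit-identical bundles.  Returns
    ``(ReferenceBundle, GroundTruth)``.
    """
    from ccisim.io import ReferenceBundle

    if n_types < 2:
        raise ValueError("need at least 2 cell types")
    if n_cells < n_types:
        raise ValueError("need at least one cell per type")
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = _default_truth(
            n_genes,
            n_types,
            rng,
            correlated_pairs=correlated_pairs,
            colocalization_specs=colocalization_specs,
            perturbation_specs=perturbation_specs,
        )
    truth.seed = seed
    base = n_cells // len(truth.cell_types)
    targets = {ct: base for ct in truth.cell_types}
    targets[truth.cell_types[0]] += n_cells - base * len(truth.cell_types)

    pool = _simulate_map(truth, targets, rng)
    order = np.argsort(pool.cell_types, kind="stable")
    pool = pool.subset(order)
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(len(pool))],
            "cell_type": pool.cell_types.astype(str),
            "x": pool.coordinates[:, 0],
            "y": pool.coordinates[:, 1],
            "region": np.asarray(pool.regions).astype(str),
        }
    )
    counts = np.zeros((n_genes, len(pool)), dtype=np.int64)
    for ct in truth.cell_types:
        idx = np.flatnonzero(cells["cell_type"] == ct)
        model = CellTypeExpressionModel(
            cell_type=ct,
            gene_names=truth.gene_names,
            marginals=truth.marginals[ct],
            sigma=truth.sigma[ct],
        )
        counts[:, idx] = draw_counts(
            model,
            len(idx),
            use_correlation=truth.sigma[ct] is not None,
            seed=int(rng.integers(2**31)),
        )
    if truth.perturbation_specs:
        delta = accumulate_delta(
            cells,
            truth.perturbation_specs,
            n_genes,
            gene_names=truth.gene_names,
            seed=int(rng.integers(2**31)),
        )
        counts = apply_delta(counts, delta)
        truth.delta_provenance = delta.provenance
    counts_df = pd.DataFrame(counts, index=truth.gene_names, columns=cells["cell_id"])

    if scenario == "paired":
        return ReferenceBundle(counts=counts_df, cells=cells, scenario="paired"), truth
    if scenario == "expression_only":
        meta = cells[["cell_id", "cell_type", "region"]].copy()
        return ReferenceBundle(counts=counts_df, cells=meta, scenario="expression_only"), truth
    if scenario == "unpaired":
        meta = cells[["cell_id", "cell_type", "region"]].copy()
        spatial_pool = _simulate_map(truth, targets, rng)
        spatial = pd.DataFrame(
            {
                "cell_id": [f"scell{i:05d}" for i in range(len(spatial_pool))],
                "cell_type": spatial_pool.cell_types.astype(str),
                "x": spatial_pool.coordinates[:, 0],
                "y": spatial_pool.coordinates[:, 1],
                "region": np.asarray(spatial_pool.regions).astype(str),
            }
        )
        return (
            ReferenceBundle(
                counts=counts_df, cells=meta, scenario="unpaired", spatial_cells=spatial
            ),
            truth,
        )
    raise ValueError(f"unknown scenario {scenario!r}")
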