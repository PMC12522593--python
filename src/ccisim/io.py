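"""Reading references and configs, writing simulated outputs.

Reference expression is a gene x cell integer count matrix as delimited text
(genes in rows, header row of cell ids) or MatrixMarket (``.mtx`` with
``genes.tsv`` and ``cells.tsv`` alongside).  Cell metadata is a TSV with
required columns ``cell_id`` and ``cell_type`` and optional ``x``, ``y``,
``region``.  Which simulation scenario applies is inferred from what is
present: coordinates on the expression cells mean a paired reference, a
separate spatial table means an unpaired one, and neither means
expression-only.

A simulation run is fully determined by one YAML parameter file plus a seed,
and every run writes a machine-readable ground-truth sidecar recording all
planted effects, because the simulator exists to benchmark with known truth.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from ccisim.colocalization import ColocalizationSpec, DEFAULT_INFLATION, NEIGHBOR_METHODS
from ccisim.domain import DEFAULT_BUFFER_RADIUS, WINDOW_METHODS
from ccisim.perturbation import PerturbationSpec

logger = logging.getLogger(__name__)

SCENARIOS = ("paired", "expression_only", "unpaired")
RESOLUTIONS = ("single_cell", "multi_cell")


@dataclass
class ReferenceBundle:
    """One reference dataset: counts, cell metadata, and the scenario."""

    counts: pd.DataFrame  # genes x cells
    cells: pd.DataFrame  # cell_id, cell_type [, x, y, region]
    scenario: str
    spatial_cells: pd.DataFrame | None = None  # unpaired scenario only

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.counts.shape[1] != len(self.cells):
            raise ValueError(
                f"counts has {self.counts.shape[1]} cell columns but metadata has "
                f"{len(self.cells)} rows"
            )
        if "cell_type" not in self.cells.columns:
            raise ValueError("cell metadata must have a cell_type column")
        if self.cells["cell_type"].isna().any() or (self.cells["cell_type"].astype(str) == "").any():
            raise ValueError("cell types must be non-empty")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(vals.dtype, np.integer) and np.any(vals != np.floor(vals)):
            raise ValueError("counts must be integers (real values are rejected, not rounded)")
        if self.scenario == "paired":
            if not {"x", "y"} <= set(self.cells.columns):
                raise ValueError("paired scenario requires x and y columns on cells")
        if self.scenario == "unpaired":
            if self.spatial_cells is None:
                raise ValueError("unpaired scenario requires a spatial cell table")
            expr_types = set(self.cells["cell_type"].astype(str))
            spat_types = set(self.spatial_cells["cell_type"].astype(str))
            if expr_types != spat_types:
                raise ValueError(
                    "unpaired spatial reference must share the expression cell-type set; "
                    f"difference: {expr_types ^ spat_types}"
                )
            if not {"x", "y"} <= set(self.spatial_cells.columns):
                raise ValueError("spatial cell table requires x and y columns")

    @property
    def gene_names(self) -> list:
        return list(self.counts.index)

    @property
    def cell_types(self) -> list:
        return sorted(set(self.cells["cell_type"].astype(str)))


def _read_counts(path: Path) -> pd.DataFrame:
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)[0].astype(str)
        cell_ids = pd.read_csv(path.parent / "cells.tsv", sep="\t", header=None)[0].astype(str)
        arr = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be integers")
        return pd.DataFrame(arr.astype(np.int64), index=genes, columns=cell_ids)
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_reference(
    expression_path,
    metadata_path,
    spatial_path=None,
) -> ReferenceBundle:
    """Load and validate a reference; the scenario is inferred.

    A spatial table forces the unpaired scenario; x/y on the metadata forces
    paired; otherwise the reference is expression-only.
    """
    expression_path = Path(expression_path)
    metadata_path = Path(metadata_path)
    counts = _read_counts(expression_path)
    cells = pd.read_csv(metadata_path, sep="\t")
    if "cell_type" not in cells.columns:
        raise ValueError(f"{metadata_path} lacks the required cell_type column")
    # region labels are categorical, whatever they look like numerically
    if "region" in cells.columns:
        cells["region"] = cells["region"].astype(str)
    spatial_cells = None
    if spatial_path is not None:
        spatial_cells = pd.read_csv(Path(spatial_path), sep="\t")
        if "region" in spatial_cells.columns:
            spatial_cells["region"] = spatial_cells["region"].astype(str)
        scenario = "unpaired"
    elif {"x", "y"} <= set(cells.columns):
        scenario = "paired"
    else:
        scenario = "expression_only"
    return ReferenceBundle(counts=counts, cells=cells, scenario=scenario, spatial_cells=spatial_cells)


@dataclass
class SimulationConfig:
    """Everything that determines one simulation run (with the seed)."""

    scenario: str = "expression_only"
    n_regions: int = 1
    grid_size: int = 20
    cells_per_region_per_type: dict = field(default_factory=dict)
    window_method: str = "delaunay"
    buffer_radius: float = DEFAULT_BUFFER_RADIUS
    min_cell_distance: float = DEFAULT_BUFFER_RADIUS
    mh_iterations: int = 500_000
    n_permutations: int = 2000
    max_cells_per_type_per_region: int = 2500
    depth_factor: float = 1.0
    evenness_nu: float = 0.0
    evenness_alpha_star: float = 0.0
    inflation_eta: float = DEFAULT_INFLATION
    neighbor_method: str = "knn"
    neighbor_param: float = 6
    use_correlation: bool = True
    region_specific_models: bool = False
    colocalization_specs: list = field(default_factory=list)
    expression_cci_specs: list = field(default_factory=list)
    gene_pair_cci_specs: list = field(default_factory=list)
    regional_specs: list = field(default_factory=list)
    output_resolution: str = "single_cell"
    n_squares: int = 100
    seed: int = 0
    cap_max_counts: bool = False
    match_depth: bool = False

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.window_method not in WINDOW_METHODS:
            raise ValueError(f"window_method must be one of {WINDOW_METHODS}")
        if self.neighbor_method not in NEIGHBOR_METHODS:
            raise ValueError(f"neighbor_method must be one of {NEIGHBOR_METHODS}")
        if self.output_resolution not in RESOLUTIONS:
            raise ValueError(f"output_resolution must be one of {RESOLUTIONS}")
        if self.depth_factor <= 0:
            raise ValueError("depth_factor must be > 0")
        if self.inflation_eta <= 0:
            raise ValueError("inflation_eta must be > 0")
        if self.mh_iterations < 1 or self.n_permutations < 1:
            raise ValueError("iteration counts must be >= 1")

    def planted_colocalization(self) -> list:
        return [
            ColocalizationSpec(type_pair=(s["type_a"], s["type_b"]), strength=float(s["strength"]))
            for s in self.colocalization_specs
        ]

    def planted_perturbations(self) -> list:
        specs = []
        for s in self.expression_cci_specs:
            specs.append(
                PerturbationSpec(
                    kind="spatial_dependence",
                    perturbed_type=s["perturbed_type"],
                    neighbor_type=s["neighbor_type"],
                    distance_threshold=float(s["distance_threshold"]),
                    region=s.get("region"),
                    genes=tuple(s["genes"]) if s.get("genes") else None,
                    gene_fraction=s.get("gene_fraction"),
                    effect_mean=float(s["effect_mean"]),
                    effect_sd=float(s.get("effect_sd", 0.0)),
                )
            )
        for s in self.gene_pair_cci_specs:
            specs.append(
                PerturbationSpec(
                    kind="gene_pair",
                    perturbed_type=s["perturbed_type"],
                    neighbor_type=s["neighbor_type"],
                    distance_threshold=float(s["distance_threshold"]),
                    region=s.get("region"),
                    gene_pair=tuple(s["gene_pair"]),
                    bidirectional=bool(s.get("bidirectional", False)),
                    effect_mean=float(s["effect_mean"]),
                    effect_sd=float(s.get("effect_sd", 0.0)),
                )
            )
        for s in self.regional_specs:
            specs.append(
                PerturbationSpec(
                    kind="regional",
                    perturbed_type=s["perturbed_type"],
                    region=s.get("region"),
                    genes=tuple(s["genes"]) if s.get("genes") else None,
                    gene_fraction=s.get("gene_fraction"),
                    effect_mean=float(s["effect_mean"]),
                    effect_sd=float(s.get("effect_sd", 0.0)),
                )
            )
        return specs


def read_config(path) -> SimulationConfig:
    """Parse a YAML parameter file, filling documented defaults.

    Unknown keys are logged and ignored with a warning; invalid enum values
    raise.  An empty file yields the all-defaults configuration.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of keys to values")
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}")
        logger.warning("ignoring unknown config keys: %s", sorted(unknown))
        raw = {k: v for k, v in raw.items() if k in known}
    return SimulationConfig(**raw)


def _spec_to_jsonable(obj):
    if isinstance(obj, (PerturbationSpec, ColocalizationSpec)):
        return {k: _spec_to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _spec_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_spec_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_simulation(
    cells: pd.DataFrame,
    counts: pd.DataFrame,
    out_dir,
    resolution: str = "single_cell",
    ground_truth: dict | None = None,
) -> dict:
    """Write one simulated dataset: metadata, counts (TSV + MatrixMarket),
    and the ground-truth sidecar of all applied effects.

    Returns the mapping of artifact name to file path.
    """
    if counts.shape[1] != len(cells):
        raise ValueError("cells and counts are not conformable")
    if resolution not in RESOLUTIONS:
        raise ValueError(f"resolution must be one of {RESOLUTIONS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    meta_path = out / "metadata.tsv"
    cells.to_csv(meta_path, sep="\t", index=False)
    files["metadata"] = meta_path
    tsv_path = out / "counts.tsv"
    counts.to_csv(tsv_path, sep="\t")
    files["counts_tsv"] = tsv_path
    mtx_path = out / "counts.mtx"
    spio.mmwrite(mtx_path, sparse.csr_matrix(counts.to_numpy()))
    (out / "genes.tsv").write_text("\n".join(map(str, counts.index)) + "\n")
    (out / "cells.tsv").write_text("\n".join(map(str, counts.columns)) + "\n")
    files["counts_mtx"] = mtx_path
    gt_path = out / "ground_truth.json"
    gt_path.write_text(json.dumps(_spec_to_jsonable(ground_truth or {}), indent=1))
    files["ground_truth"] = gt_path
    return files
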