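# ccisim

Simulate spatially resolved transcriptomics (SRT) data with known
cell–cell interaction (CCI) ground truth.

Benchmarking CCI analysis tools — colocalization tests, neighbor-dependent
expression models, ligand–receptor inference — requires data where the
interactions are *known*, and real tissue never provides that. `ccisim`
generates synthetic SRT datasets that preserve the spatial and
transcriptomic character of a reference while planting controlled
interaction effects, and records every planted effect so downstream methods
can be scored against exact truth. It accepts three kinds of reference:

1. **paired** — expression and coordinates from the same cells (e.g.,
   SeqFISH+, MERFISH, Xenium),
2. **expression-only** — scRNA-seq/snRNA-seq, with spatial structure
   generated de novo, and
3. **unpaired** — an expression reference plus a spatial map from another
   slide or technology sharing the same cell types.

## The model in brief

**Stage 1 (spatial map).** The tissue window is either the unit square —
partitioned into K connected regions by a seeded random walk on a B×B grid —
or estimated from reference coordinates by a buffered Delaunay triangulation
whose outer frame follows concave tissue outlines. Per cell type, cell
density is an inhomogeneous Poisson point process with log-polynomial
intensity log λ_c(x, y) = β₀ + β₁x + … (degree ≤ 3), fitted by a
Berman–Turner Poisson GLM and sampled by accept/reject with probability
min(1, λ(x, y)/c). Colocalization is planted by inflating the candidate pool
by λ = (Σ_j η(1+|a_j|))^(1+ν) and selecting cells with logistic probability
logit(P_ic) = μ₁ + μ₂ + μ₃ + α_c, where the μ terms accumulate
neighborhood-density effects weighted by the interaction strengths a_j and
α_c pins the per-type mean selection probability to target/pool.

**Stage 2 (expression).** Per cell type, each gene follows a zero-inflated
negative binomial (zero proportion π, mean m, dispersion r), coupled across
genes by a Gaussian copula: Z ~ N(0, Σ), U = Φ(Z), Y_g = F_g⁻¹(U_g). CCI
and regional effects accumulate in a cells × genes matrix Δ of
N(μ, σ²) draws — neighbor-dependent shifts, ligand–receptor pair shifts
(optionally bidirectional with a shared draw), and regional shifts — and the
counts are updated as round(expm1(log1p(Y) + Δ)), floored at zero, with
optional extreme-value capping and exact depth matching.

Estimators for everything the simulator plants are built in: permutation
neighbor-enrichment for colocalization, log2-fold-change statistics for
neighbor-dependent expression and gene-pair co-expression, plus fidelity
metrics (window coverage, bias, effect recovery) and benchmarking scores
(balanced accuracy, permutation-normalized F1). See `docs/methods.md` for
the full account.

## Worked example

Plant same-type attraction (strength a = +3) among `typeA` cells on a
500-cell map, then recover it with the built-in enrichment estimator:

```python
from ccisim import (generate_reference, ColocalizationSpec,
                    build_neighbor_graph, estimate_colocalization)

bundle, truth = generate_reference(
    "paired", n_cells=500, n_genes=100, n_types=3, seed=7,
    colocalization_specs=[ColocalizationSpec(("typeA", "typeA"), 3.0)],
)
graph = build_neighbor_graph(bundle.cells[["x", "y"]].to_numpy(), "knn", 6)
for est in estimate_colocalization(graph, bundle.cells["cell_type"].to_numpy(),
                                   n_perm=1000, seed=1):
    print(f"{est.type_pair[0]:>5s}-{est.type_pair[1]:<5s} "
          f"enrichment={est.enrichment:+.3f}  p={est.p_value:.4f}")
```

```
typeA-typeA enrichment=+0.552  p=0.0010
typeA-typeB enrichment=-0.251  p=0.0010
typeA-typeC enrichment=-0.341  p=0.0010
typeB-typeB enrichment=+0.042  p=0.6124
typeB-typeC enrichment=+0.131  p=0.0160
typeC-typeC enrichment=+0.077  p=0.3137
```

The planted typeA–typeA attraction comes back as a strongly positive
log2 enrichment (observed A–A adjacencies ≈ 1.47× the permutation
expectation, p = 0.001); the compensating negative cross-type scores appear
because clustering the A cells necessarily pulls them away from everyone
else, and the remaining pairs are null.

The command line mirrors the library:

```bash
ccisim fixtures --scenario paired --out ref/         # synthetic reference
ccisim simulate --config params.yaml --out sim/ \
       --expression ref/counts.tsv --metadata ref/metadata.tsv
ccisim estimate --config params.yaml --out est/ \
       --expression ref/counts.tsv --metadata ref/metadata.tsv
```

`simulate` writes `metadata.tsv`, `counts.tsv`, `counts.mtx` (+ gene/cell
sidecars), and `ground_truth.json` — the record of every applied effect.

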