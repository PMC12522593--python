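# Methods

`ccisim` simulates spatially resolved transcriptomics (SRT) data in two
stages — a spatial map of typed cells, then a count matrix for those cells —
with every cell–cell interaction (CCI) effect planted by the simulator
recorded as ground truth. This note documents the models, the numerical
choices, and what the validation experiments do and do not establish.

## Stage 1: the spatial map

### Windows and regions

With no spatial reference, the window is the unit square. For `K > 1`
regions it is divided into a `B x B` pixel grid (`B = 20` by default; larger
`B` gives smoother boundaries) and grown into `K` connected regions:
`K` distinct border pixels seed the regions, and each still-active region
claims one uniformly chosen unassigned edge-neighbor per round, cycling
region by region until the grid is covered. Cyclic one-pixel growth makes
region sizes similar without a rebalancing step. Starting pixels are allowed
to be adjacent.

With a spatial reference, the window is estimated from the cell centers.
The default method pads each center with four buffer points at radius
`0.0005` (reference units, at angles 0/90/180/270°), triangulates the
augmented set (Delaunay), removes triangles with an edge longer than
mean + 3 SD of the edge-length distribution, and takes the boundary of the
union of surviving triangles — holes are preserved, and the buffer
guarantees every center is strictly inside. `rectangle`, `convex`, and
`sectioned_convex` (2–5 equal-width vertical slices, convex hull per slice,
union) are cheaper approximations. Per-region windows may overlap slightly
because of buffering; each overlap polygon is assigned wholly to one of its
two regions, chosen uniformly at random (seeded).

### Cell placement

Per cell type, reference cell density is modeled as an inhomogeneous
Poisson point process with log-polynomial intensity (degree ≤ 3 when the
type has more than ten cells, degree ≤ 2 otherwise — the cubic surface
overfits small types; exactly ten cells gets the quadratic, the conservative
side of an unstated boundary). The fit is a Berman–Turner weighted Poisson
GLM on a 32×32 quadrature grid. A singular cubic fit falls back to the
quadratic. Note the monomials are strongly collinear on the unit interval,
so individual coefficients are weakly identified even when the fitted
intensity surface is accurate; diagnostics should compare surfaces, not
coefficients.

New coordinates are sampled with the accept/reject rule
`accept with probability min(1, lambda(x, y) / c)`, where
`c = exp(max log-intensity over a 200×200 grid) * 1.05`. For a Poisson
process (no interaction terms) each accepted uniform proposal is an
independent draw from the normalized intensity, so the sampler runs the
500,000-proposal default budget as vectorized accept/reject births rather
than a serial birth/death/shift chain — the chain's extra move types change
nothing about the stationary distribution here and cost two orders of
magnitude in speed. The accepted set is thinned uniformly (acceptance
already applied the intensity weighting) or topped up with further births
until exactly `n_target` points remain.

Overlapping cells (closer than `min_cell_distance`, default equal to the
buffer radius 0.0005 since no other default is established) are resolved by
visiting points in random order and keeping a point only if no kept point is
within the minimum distance: within each conflict cluster the survivor is
uniform at random, every removed point has a kept point nearby, and the
operation is idempotent.

### Colocalization: estimation

Neighbor graphs come in three flavors: symmetrized kNN (default k = 6),
Delaunay (optionally pruned by the mean + 3 SD edge rule), and fixed-radius.
For each unordered cell-type pair, the observed number of adjacent pairs is
compared with its mean over 2,000 (default) random relabelings of the
nodes; the enrichment score is `log2(observed / expected)` with a 0.5
pseudo-count guarding empty cells (flagged when the expectation itself is
zero), and the p-value is the two-sided permutation tail probability with
the standard +1 correction. Unordered pairs are reported.

### Colocalization: simulation

Planting attraction or inhibition uses pool inflation plus logistic
selection. The pool holds `lambda = (sum_j eta (1 + |a_j|))^(1 + nu)` times
the target count (`eta` defaults to 1.5; with no interaction specs the
empty sum degenerates and `lambda = eta^(1+nu)`, floored at 1). Cell `i` of
type `c` is selected with log-odds

    mu1 + mu2 + mu3 + alpha_c

where `mu1` sums `a_j * d_{i,c}` over same-type patterns, `mu2` sums cross-
type terms, `mu3 = alpha* · d*_i` controls evenness, and `alpha_c` is solved
by bisection (Brent, tolerance 1e-8; the mean of logistic curves is strictly
increasing in the intercept, so the root is unique) so that the mean
selection probability equals `target_c / pool_c`. Exactly `target_c` cells
are drawn without replacement with probability-proportional sequential
draws.

Two numerical choices matter here and were settled by measurement:

* **Densities are neighbor counts, not fractions.** `d_{i,t}` is the number
  of type-`t` cells among `i`'s neighbors. Normalizing by the degree
  compresses the density range so far that strengths of the magnitude
  estimated from tissue (≈ 2–3 on this scale) produce no detectable
  clustering; with counts, planted `a = ±3` on 500-cell maps is recovered
  with the right sign at p < 0.05 in 20/20 seeds.
* **Types are selected sequentially.** If every type's densities are
  computed once on the raw pool, mutual cross-type attraction fails: each
  type chases the other's *pool* density peaks, which are mostly discarded
  by selection. Types are therefore processed in order, each seeing the
  already-selected cells of earlier types and the pool of later ones.
  Cross-type effects thereby act on cells that will actually exist.

When estimated enrichments are replayed as selection strengths, the mapping
is the identity: no calibration formula linking the permutation enrichment
`beta` to the selection strength `a` is established, so estimated effect
sizes are used as-is and this is an interpretation to keep in mind when
comparing absolute magnitudes.

## Stage 2: expression

### Marginals

Each gene in each cell type (optionally each region) follows a zero-inflated
negative binomial: structural-zero probability `pi`, NB mean `m`, and
dispersion `r` with `Var = m + m²/r`. Fitting is direct MLE (Nelder–Mead on
the `(logit pi, log m, log r)` chart). The fallback ladder
ZINB → NB → ZIP → Poisson is realized as BIC selection among the candidates
that are identifiable for the data at hand (no zeros rules out the
zero-inflated families; an all-zero gene collapses to `pi = 1`); boundary
estimates (`pi < 1e-4`, `r` at the Poisson cap) also demote the family.
For large references, fitting uses a uniform subsample of at most 2,500
cells per cell type per region — accuracy gains beyond that are marginal
and the cap keeps fitting time flat.

### Copula correlation

Gene–gene dependence is a Gaussian copula: latent `Z ~ N(0, Sigma)`,
`U = Phi(Z)`, `Y_g = F_g^{-1}(U_g)`. Drawing counts this way preserves each
marginal exactly for any `Sigma` (validated to Monte-Carlo error at
n = 5000). `depth_factor` rescales every NB mean, leaving `pi` untouched —
the minimal reading of a sequencing-depth multiplier; totals scale linearly.

Estimating `Sigma` from counts must invert the copula through heavy ties.
The randomized distributional transform (`u = F(y-1) + V·pmf(y)`,
`z = Phi^{-1}(u)`) is simple but attenuated: with typical zero inflation it
recovers a planted latent correlation of 0.9 as ≈ 0.81 at n = 2000. The
default estimator instead uses conditional-mean scores
`m(y) = E[z | y] = (phi(l) − phi(u)) / (F(y) − F(y−1))` and the marginal's
retained latent variance `lambda² = sum_y P(y) m(y)²`, estimating
`rho = E[m_g m_h] / (lambda_g² lambda_h²)` (a first-order deattenuation;
exact for continuous margins). Measured recovery at n = 2000 is
0.29 / 0.60 / 0.93 for planted 0.3 / 0.6 / 0.9. Estimates are clipped to
±0.999, constant genes get identity rows, and an indefinite matrix is
projected to the nearest correlation matrix (eigenvalue clipping). The
randomized transform remains available as `method="randomized"`.
No shrinkage is applied by default: the goal is to reproduce the empirical
dependence of the reference.

### CCI effects on expression

**Estimation.** For a sender→receiver type pair, receivers adjacent to at
least one sender form the neighbor group; the per-gene effect is the log2
fold change of group means with a pseudo-count of 1 (guarding sparse
genes), and p-values come from shuffling the group assignment. For gene
pairs (a ligand–receptor list narrows the search space), the statistic is
the log2 fold change of the mean sender-gene × receiver-gene product over
adjacent versus non-adjacent sender–receiver cell pairs, with the null
redrawing which pairs are adjacent. Groups smaller than two cells are
skipped with a log entry.

**Injection.** All effects accumulate in an all-zero cells × genes matrix
Δ. Neighbor-dependent specs add `N(mu, sigma²)` draws at the chosen genes
of perturbed-type cells in the region that have a neighbor-type cell within
the Euclidean distance threshold (a cell is never its own neighbor); the
draw is independent per (cell, gene) except the bidirectional gene-pair
rule, where the partner cell's paired gene receives the same drawn value —
the one sharing rule that is explicit. Regional specs hit all matching
cells unconditionally. Genes may be named or drawn as a fraction of the
panel (uniform, without replacement, recorded). Provenance records every
affected index set and every drawn effect, and all names are validated
before any mutation.

**Update.** `updated = expm1(log1p(initial) + Δ*)`, floored at zero. The
`log1p` transform is an interpretation: effects are "added to log counts",
but zeros must be able to respond to positive perturbations while staying
zero under negative ones, which plain `log` cannot do. Optional
constraints: a cap at `max(5 × the 97.5th percentile of all initial
entries, max initial)` (the percentile is global over the matrix — the
per-gene reading is also defensible but not taken), and depth matching.
Nearest-integer rounding cannot restore a total on coarse counts (all
entries sharing a value jump together as the scale factor moves), so depth
matching rounds by largest remainder: floor everything, then give the
missing units to the entries with the largest fractional parts. This
conserves the total exactly and is why the depth-match check reads 0.0%.
Without depth matching, plain half-away-from-zero rounding applies, which
makes the zero-Δ pipeline exactly the identity.

One consequence of integer rounding worth knowing: for a gene whose counts
are mostly 0, a planted `mu = 0.5` on the log1p scale turns `0 → 1`
(a realized doubling of `y+1`, not ×e^0.5). The *realized* effect on
near-zero genes therefore exceeds the nominal one. Calibration experiments
plant effects on well-expressed genes, where the nominal and realized
effects agree; on sparse genes the simulator is still correct, but the
nominal `mu` understates what is in the data.

## Multi-cell output and metrics

Spot-level data tiles the window's bounding box with the smallest `s × s`
layout with `s² ≥ n_squares` (squares of equal side `max(width, height)/s`),
sums expression per square, and places the spot at the square center.
Squares intersecting the window are kept even when empty; squares wholly
outside the tissue are dropped. Aggregation conserves totals exactly.

Fidelity metrics: window coverage percentages (total, overlap, reference-
only, simulation-only, all relative to the reference area), absolute and
relative bias with medians (relative bias flagged undefined at zero
reference), and Pearson r / MSE for effect-size recovery. Benchmark
metrics for ligand–receptor predictions over a universe of
(ligand, receptor, sender, receiver) keys: balanced accuracy
(mean of sensitivity and specificity) and F1 normalized by the mean F1 of
100 size-preserving label shuffles, with F1 and normalized F1 both zero
when there are no true positives. The default universe is the supplied LR
list × ordered type pairs; it is configurable because the denominator of
the specificity depends on it. No ligand–receptor database ships with the
package; users supply their own two-column list.

## The synthetic reference generator

`generate_reference` produces desk-scale bundles (default 500 cells × 200
genes, three types — comparable to a small imaging field of view) for all
three scenarios, with every generating parameter recorded: marginals drawn
from log-normal means clipped to [0.2, 60], dispersion U(0.8, 4), zero
inflation U(0.05, 0.35); optional planted latent correlations,
colocalization strengths, and perturbation specs. Identical seeds give
bit-identical bundles. What it does *not* emulate: continuous within-type
heterogeneity, spatial gradients in expression beyond the planted effects,
segmentation noise, or platform-specific artifacts — so passing recovery
tests demonstrates internal consistency of the estimators and generators,
not performance on any particular tissue or platform.

## Validation experiment design

`ccisim.validation` holds the recovery experiments run by both the test
suite and `scripts/acceptance.py`. Problem sizes (500-cell maps, 20 seeds
for detection rates, n = 5000 for moment checks, 300–500 permutations) keep
each experiment within seconds to ~2 minutes on one core with comfortable
statistical margins. Two designs deserve explanation:

* The ZINB recovery experiment draws parameters from `pi ∈ [0.2, 0.4]`,
  `mean ∈ [10, 40]`, `dispersion ∈ [1, 2.5]`. Outside this regime the ±10%
  per-gene check fails for a reason that has nothing to do with the code:
  the MLE's own sampling error at n = 5000 exceeds 10% for weakly expressed,
  heavily zero-inflated genes (refitting from the true parameters lands on
  the same estimate). The experiment therefore measures estimator
  correctness where the parameters are identifiable.
* The gene-pair co-expression monotonicity check reads out the mean
  product-enrichment statistic rather than a plain Pearson correlation.
  With a shared constant effect (sd = 0), interacting pairs shift jointly in
  mean but gain no within-group correlation, and a correlation computed
  across a mixed cell population has signal of order 0.005–0.05 against
  noise of order 0.01 over the stated effect grid — empirically flat. The
  product enrichment grows near-linearly in the effect size (0.01 → 0.74
  over mu = 0 … 0.5) and is the calibrated co-expression readout.

## Known limitations

* Cross-type colocalization depends on the processing order of types
  (later types see earlier types' final positions); with many interacting
  pairs the order is the `targets` iteration order.
* The intensity model is a global polynomial; multimodal densities with
  more than a few modes need region-stratified fitting.
* The copula deattenuation is first-order and slightly overshoots at
  `|rho| > 0.9`.
* Replayed colocalization strengths use the identity mapping from estimated
  enrichments; absolute strengths are comparable only within one neighbor-
  graph configuration.
* Counts are treated as raw integers throughout; no normalization layer is
  provided or assumed.
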