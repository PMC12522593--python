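"""CCI and regional effects on expression: estimation and injection.

Estimation compares receiver cells adjacent to at least one sender against
receivers with no sender neighbor (log2 fold change of group means with a
permutation p-value), and, for ligand-receptor style gene pairs, adjacent
versus non-adjacent sender-receiver cell pairs on the product of the two
genes' counts.

Injection accumulates all planted effects into a cells x genes change
matrix Delta on the log scale: neighbor-dependent shifts (cell type k near
type l within distance c), gene-pair co-expression shifts (optionally
bidirectional with a shared drawn effect), and regional shifts.  The final
Delta* is added to log1p-transformed counts, floored at zero, optionally
capped and depth-matched, and rounded back to integers.  Using log1p rather
than log lets a positive perturbation lift zero counts while a negative one
leaves them at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ccisim.colocalization import NeighborGraph

logger = logging.getLogger(__name__)

PERTURBATION_KINDS = ("spatial_dependence", "gene_pair", "regional")


@dataclass(frozen=True)
class PerturbationSpec:
    """One planted effect: who is perturbed, where, by how much.

    ``kind`` selects the rule: "spatial_dependence" perturbs genes of
    perturbed_type cells that have a neighbor_type cell within
    distance_threshold; "gene_pair" perturbs gene_pair[0] in such cells (and,
    if bidirectional, gene_pair[1] in the partner cells with the same drawn
    effect); "regional" perturbs genes of perturbed_type cells in the region
    unconditionally.  Effects are drawn from N(effect_mean, effect_sd^2).
    Genes may be named explicitly or drawn as a fraction of the panel.
    """

    kind: str
    perturbed_type: str
    effect_mean: float
    effect_sd: float = 0.0
    region: object | None = None
    neighbor_type: str | None = None
    distance_threshold: float | None = None
    genes: tuple | None = None
    gene_fraction: float | None = None
    gene_pair: tuple | None = None
    bidirectional: bool = False

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be >= 0")
        if self.kind in ("spatial_dependence", "gene_pair"):
            if self.neighbor_type is None or self.distance_threshold is None:
                raise ValueError(f"{self.kind} specs need neighbor_type and distance_threshold")
        if self.kind == "gene_pair":
            if self.gene_pair is None or len(self.gene_pair) != 2:
                raise ValueError("gene_pair specs need a (gene_m, gene_n) pair")
        elif self.genes is None:
            if self.gene_fraction is None or not 0 < self.gene_fraction <= 1:
                raise ValueError("provide genes or a gene_fraction in (0, 1]")


@dataclass
class DeltaMatrix:
    """Accumulated log-scale changes, cells x genes, with provenance."""

    values: np.ndarray
    provenance: list = field(default_factory=list)

    @property
    def shape(self):
        return self.values.shape


def _group_log2fc(counts: np.ndarray, in_group: np.ndarray, pseudo: float = 1.0) -> np.ndarray:
    """log2 of (mean in group + 1) / (mean out of group + 1), per gene."""
    m1 = counts[:, in_group].mean(axis=1)
    m0 = counts[:, ~in_group].mean(axis=1)
    return np.log2((m1 + pseudo) / (m0 + pseudo))


def _receiver_neighbor_flag(graph: NeighborGraph, types: np.ndarray, sender: str, receiver: str) -> tuple[np.ndarray, np.ndarray]:
    """Receiver cell indices and, per receiver, whether a sender is adjacent."""
    types = np.asarray(types)
    recv_idx = np.flatnonzero(types == receiver)
    has_sender = np.zeros(len(types), dtype=bool)
    if graph.n_edges:
        ea, eb = graph.edges[:, 0], graph.edges[:, 1]
        sa = types[ea] == sender
        sb = types[eb] == sender
        np.logical_or.at(has_sender, eb[sa], True)
        np.logical_or.at(has_sender, ea[sb], True)
    return recv_idx, has_sender[recv_idx]


def estimate_spatial_dependence(
    counts: np.ndarray,
    cells: pd.DataFrame,
    graph: NeighborGraph,
    sender: str,
    receiver: str,
    gene_names: list | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-gene CCI effect of sender proximity on receiver expression.

    Receivers adjacent to >= 1 sender form the neighbor group; the statistic
    is the log2 fold change of group means (pseudo-count 1).  P-values come
    from shuffling the neighbor flag among receiver cells.  Returns an empty
    frame (with a log entry) when either group has fewer than 2 cells.
    """
    counts = np.asarray(counts, dtype=float)
    types = np.asarray(cells["cell_type"])
    G = counts.shape[0]
    if gene_names is None:
        gene_names = list(range(G))
    recv_idx, flag = _receiver_neighbor_flag(graph, types, sender, receiver)
    cols = ["sender", "receiver", "gene", "log2fc", "p_value"]
    if flag.sum() < 2 or (~flag).sum() < 2:
        logger.warning(
            "sender=%s receiver=%s: neighbor/non-neighbor groups too small (%d/%d); skipped",
            sender, receiver, int(flag.sum()), int((~flag).sum()),
        )
        return pd.DataFrame(columns=cols)
    sub = counts[:, recv_idx]
    obs = _group_log2fc(sub, flag)
    rng = np.random.default_rng(seed)
    n_r, k = len(recv_idx), int(flag.sum())
    # permutation of the neighbor flag with group sizes preserved
    F = np.argsort(rng.random((n_perm, n_r)), axis=1) < k  # (n_perm, n_r)
    row_tot = sub.sum(axis=1, keepdims=True)
    M1 = sub @ F.T / k  # (G, n_perm)
    M0 = (row_tot - sub @ F.T) / (n_r - k)
    perm = np.log2((M1 + 1.0) / (M0 + 1.0))
    p = (1 + np.sum(np.abs(perm) >= np.abs(obs)[:, None], axis=1)) / (n_perm + 1)
    return pd.DataFrame(
        {"sender": sender, "receiver": receiver, "gene": gene_names, "log2fc": obs, "p_value": p}
    )


def estimate_gene_pair_cci(
    counts: np.ndarray,
    cells: pd.DataFrame,
    graph: NeighborGraph,
    pair_list: pd.DataFrame,
    sender: str,
    receiver: str,
    gene_names: list,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Co-expression of gene pairs across adjacent sender-receiver cells.

    For each (ligand, receptor) pair the statistic is the log2 fold change of
    the mean product ligand(sender) x receptor(receiver) over adjacent cell
    pairs versus non-adjacent ones; the null redraws which sender-receiver
    pairs are adjacent.  Pairs whose genes are missing are skipped with a
    log entry.
    """
    counts = np.asarray(counts, dtype=float)
    types = np.asarray(cells["cell_type"])
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    s_idx = np.flatnonzero(types == sender)
    r_idx = np.flatnonzero(types == receiver)
    cols = ["sender", "receiver", "gene_m", "gene_n", "log2fc_product", "p_value"]
    if len(pair_list) == 0 or len(s_idx) == 0 or len(r_idx) == 0:
        return pd.DataFrame(columns=cols)
    pos_s = -np.ones(len(types), dtype=int)
    pos_s[s_idx] = np.arange(len(s_idx))
    pos_r = -np.ones(len(types), dtype=int)
    pos_r[r_idx] = np.arange(len(r_idx))
    adj = []
    if graph.n_edges:
        for a, b in graph.edges:
            if pos_s[a] >= 0 and pos_r[b] >= 0:
                adj.append((pos_s[a], pos_r[b]))
            if pos_s[b] >= 0 and pos_r[a] >= 0:
                adj.append((pos_s[b], pos_r[a]))
    adj = np.array(sorted(set(adj)), dtype=int).reshape(-1, 2)
    n_adj = len(adj)
    N = len(s_idx) * len(r_idx)
    if n_adj == 0 or N - n_adj == 0:
        logger.warning("no adjacent (or no non-adjacent) %s-%s pairs; skipped", sender, receiver)
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    perm_flat = np.empty((n_perm, n_adj), dtype=int)
    for p_i in range(n_perm):
        perm_flat[p_i] = rng.choice(N, size=n_adj, replace=False)
    perm_s = perm_flat // len(r_idx)
    perm_r = perm_flat % len(r_idx)
    rows = []
    lig_col, rec_col = pair_list.columns[:2]
    for _, pr in pair_list.iterrows():
        gm, gn = pr[lig_col], pr[rec_col]
        if gm not in name_to_idx or gn not in name_to_idx:
            logger.warning("gene pair (%s, %s) absent from the matrix; skipped", gm, gn)
            continue
        xm = counts[name_to_idx[gm], s_idx]
        xn = counts[name_to_idx[gn], r_idx]
        total = xm.sum() * xn.sum()
        a = float(np.sum(xm[adj[:, 0]] * xn[adj[:, 1]]))
        mean_adj = a / n_adj
        mean_non = (total - a) / (N - n_adj)
        obs = np.log2((mean_adj + 1.0) / (mean_non + 1.0))
        a_p = np.sum(xm[perm_s] * xn[perm_r], axis=1)
        m1 = a_p / n_adj
        m0 = (total - a_p) / (N - n_adj)
        perm_stat = np.log2((m1 + 1.0) / (m0 + 1.0))
        p = float((1 + np.sum(np.abs(perm_stat) >= abs(obs))) / (n_perm + 1))
        rows.append((sender, receiver, gm, gn, float(obs), p))
    return pd.DataFrame(rows, columns=cols)


def _resolve_genes(spec: PerturbationSpec, gene_names: list, rng: np.random.Generator) -> np.ndarray:
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    if spec.genes is not None:
        missing = [g for g in spec.genes if g not in name_to_idx]
        if missing:
            raise ValueError(f"unknown gene(s) {missing} in perturbation spec")
        return np.array([name_to_idx[g] for g in spec.genes], dtype=int)
    n_pick = max(1, int(round(spec.gene_fraction * len(gene_names))))
    return np.sort(rng.choice(len(gene_names), size=n_pick, replace=False))


def _qualifying_cells(
    cells: pd.DataFrame,
    spec: PerturbationSpec,
    perturbed: str,
    neighbor: str,
) -> tuple[np.ndarray, dict]:
    """Indices of perturbed-type cells in the region with a neighbor-type cell
    within the distance threshold, plus each one's nearest such partner."""
    types = np.asarray(cells["cell_type"])
    regions = np.asarray(cells["region"]) if "region" in cells else np.full(len(types), None)
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    k_mask = types == perturbed
    if spec.region is not None:
        k_mask &= regions == spec.region
    k_idx = np.flatnonzero(k_mask)
    l_idx = np.flatnonzero(types == neighbor)
    if len(k_idx) == 0 or len(l_idx) == 0 or (perturbed == neighbor and len(l_idx) < 2):
        return np.array([], dtype=int), {}
    tree = cKDTree(xy[l_idx])
    dist, nearest = tree.query(xy[k_idx], k=2 if perturbed == neighbor else 1)
    if perturbed == neighbor:
        # a cell is not its own neighbor: take the nearest *other* cell
        self_first = dist[:, 0] == 0.0
        d = np.where(self_first, dist[:, 1], dist[:, 0])
        nn = np.where(self_first, nearest[:, 1], nearest[:, 0])
    else:
        d, nn = dist, nearest
    ok = d <= spec.distance_threshold
    qual = k_idx[ok]
    partner = {int(c): int(l_idx[j]) for c, j in zip(qual, nn[ok])}
    return qual, partner


def accumulate_delta(
    cells: pd.DataFrame,
    specs: list[PerturbationSpec],
    n_genes: int,
    gene_names: list | None = None,
    seed: int | None = None,
) -> DeltaMatrix:
    """Sum all planted effects into the cells x genes change matrix Delta*.

    Every spec contributes an independent N(mu, sigma^2) draw per affected
    (cell, gene) entry, except the bidirectional gene-pair rule, where the
    partner cell's gene receives the same drawn value as its interacting
    cell.  All names are validated before anything is mutated; provenance
    records the affected indices and drawn effects per spec.
    """
    if gene_names is None:
        gene_names = list(range(n_genes))
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    types = set(np.asarray(cells["cell_type"]).tolist())
    regions = set(np.asarray(cells["region"]).tolist()) if "region" in cells else set()
    rng = np.random.default_rng(seed)
    # validate everything first
    for spec in specs:
        if spec.perturbed_type not in types:
            raise ValueError(f"unknown cell type {spec.perturbed_type!r}")
        if spec.neighbor_type is not None and spec.neighbor_type not in types:
            raise ValueError(f"unknown cell type {spec.neighbor_type!r}")
        if spec.region is not None and regions and spec.region not in regions:
            raise ValueError(f"unknown region {spec.region!r}")
        if spec.kind == "gene_pair":
            for g in spec.gene_pair:
                if g not in gene_names:
                    raise ValueError(f"unknown gene {g!r}")
    delta = np.zeros((len(cells), n_genes))
    provenance = []
    for sid, spec in enumerate(specs):
        record = {"spec_id": sid, "kind": spec.kind, "spec": spec}
        if spec.kind == "regional":
            types_arr = np.asarray(cells["cell_type"])
            mask = types_arr == spec.perturbed_type
            if spec.region is not None and "region" in cells:
                mask &= np.asarray(cells["region"]) == spec.region
            cell_idx = np.flatnonzero(mask)
            gidx = _resolve_genes(spec, gene_names, rng)
            eff = rng.normal(spec.effect_mean, spec.effect_sd, size=(len(cell_idx), len(gidx)))
            delta[np.ix_(cell_idx, gidx)] += eff
            record.update(cells=cell_idx, genes=gidx, effects=eff)
        elif spec.kind == "spatial_dependence":
            qual, _ = _qualifying_cells(cells, spec, spec.perturbed_type, spec.neighbor_type)
            gidx = _resolve_genes(spec, gene_names, rng)
            eff = rng.normal(spec.effect_mean, spec.effect_sd, size=(len(qual), len(gidx)))
            delta[np.ix_(qual, gidx)] += eff
            record.update(cells=qual, genes=gidx, effects=eff)
        else:  # gene_pair
            gm = gene_names.index(spec.gene_pair[0])
            gn = gene_names.index(spec.gene_pair[1])
            qual_k, _ = _qualifying_cells(cells, spec, spec.perturbed_type, spec.neighbor_type)
            eff_k = rng.normal(spec.effect_mean, spec.effect_sd, size=len(qual_k))
            delta[qual_k, gm] += eff_k
            record.update(cells=qual_k, genes=np.array([gm]), effects=eff_k)
            if spec.bidirectional:
                qual_l, partner_l = _qualifying_cells(
                    cells, spec, spec.neighbor_type, spec.perturbed_type
                )
                draw_of = {int(c): e for c, e in zip(qual_k, eff_k)}
                # the partner's drawn value is shared; partners outside the
                # qualifying set (e.g., other region) fall back to a new draw
                eff_l = np.array(
                    [
                        draw_of.get(partner_l[int(c)], rng.normal(spec.effect_mean, spec.effect_sd))
                        for c in qual_l
                    ]
                )
                delta[qual_l, gn] += eff_l
                record.update(cells_bidirectional=qual_l, gene_bidirectional=gn, effects_bidirectional=eff_l)
        provenance.append(record)
    return DeltaMatrix(values=delta, provenance=provenance)


def apply_delta(
    initial_counts: np.ndarray,
    delta: DeltaMatrix | np.ndarray,
    cap_max: bool = False,
    match_depth: bool = False,
) -> np.ndarray:
    """Apply Delta* to the initial counts on the log1p scale.

    updated = expm1(log1p(initial) + Delta*), floored at zero so negative
    perturbations cannot push zeros negative; optionally capped at
    max(5 x the 97.5th percentile of the initial matrix, max initial) and
    rescaled so the total count matches the initial total; finally rounded
    half-away-from-zero to integers.  ``initial_counts`` is genes x cells
    and Delta* is cells x genes.
    """
    initial = np.asarray(initial_counts, dtype=float)
    d = delta.values if isinstance(delta, DeltaMatrix) else np.asarray(delta, dtype=float)
    if d.shape != initial.T.shape:
        raise ValueError(f"delta shape {d.shape} not conformable with counts {initial.shape}")
    updated = np.expm1(np.log1p(initial) + d.T)
    updated = np.maximum(updated, 0.0)
    if cap_max:
        cap = max(5.0 * float(np.quantile(initial, 0.975)), float(initial.max()))
        updated = np.minimum(updated, cap)
    if match_depth and updated.sum() > 0:
        # nearest-integer rounding after rescaling cannot hit the target
        # total on coarse counts (whole classes of equal values jump at
        # once), so round by largest remainder: floor everything, then give
        # the missing units to the entries closest to the next integer.
        # This conserves the total exactly.
        target = int(round(float(initial.sum())))
        w = updated * (target / updated.sum())
        out = np.floor(w)
        frac = (w - out).ravel()
        deficit = int(round(target - out.sum()))
        if deficit > 0:
            idx = np.argpartition(-frac, deficit - 1)[:deficit]
            out.ravel()[idx] += 1
        return out.astype(np.int64)
    return np.floor(updated + 0.5).astype(np.int64)
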