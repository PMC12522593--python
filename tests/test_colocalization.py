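"""Neighbor graphs, permutation enrichment, pool inflation, CCI selection."""

import numpy as np
import pytest
from scipy import stats

from ccisim import (
    ColocalizationSpec,
    allocate_uniform,
    build_neighbor_graph,
    compute_inflation_ratio,
    estimate_colocalization,
    select_cells_with_cci,
)


class TestNeighborGraph:
    def test_knn_collinear_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        g = build_neighbor_graph(pts, method="knn", parameter=1)
        assert g.edge_set() == {(0, 1), (1, 2)}

    def test_distance_below_min_separation_empty(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        g = build_neighbor_graph(pts, method="distance", parameter=0.5)
        assert g.n_edges == 0

    def test_delaunay_square_corners(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        g = build_neighbor_graph(pts, method="delaunay", parameter=0)
        assert g.n_edges == 5  # 4 sides + 1 diagonal

    def test_knn_symmetrized(self):
        # asymmetric nearest neighbors: an edge exists if either side picks it
        pts = np.array([[0.0, 0.0], [0.4, 0.0], [1.0, 0.0]])
        g = build_neighbor_graph(pts, method="knn", parameter=1)
        assert (1, 2) in g.edge_set()  # 2's nearest is 1, though 1's is 0

    def test_k_too_large_rejected(self):
        pts = np.random.default_rng(0).random((5, 2))
        with pytest.raises(ValueError):
            build_neighbor_graph(pts, method="knn", parameter=5)


class TestEnrichment:
    def test_null_labels_calibrated(self):
        rng = np.random.default_rng(1)
        pts = rng.random((300, 2))
        types = rng.choice(["A", "B"], size=300)
        g = build_neighbor_graph(pts, method="knn", parameter=6)
        res = estimate_colocalization(g, types, n_perm=500, seed=2)
        assert np.median([abs(r.enrichment) for r in res]) < 0.2
        assert all(np.isfinite(r.enrichment) for r in res)

    def test_null_pvalues_uniform_over_replicates(self):
        rng = np.random.default_rng(3)
        pvals = []
        for rep in range(40):
            pts = rng.random((150, 2))
            types = rng.choice(["A", "B"], size=150)
            g = build_neighbor_graph(pts, method="knn", parameter=5)
            res = estimate_colocalization(g, types, n_perm=200, seed=rep)
            pvals.extend(r.p_value for r in res)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_cluster_enriched(self):
        rng = np.random.default_rng(4)
        clustered = rng.random((60, 2)) * 0.25  # type A packed in a corner
        background = rng.random((240, 2))
        pts = np.vstack([clustered, background])
        types = np.array(["A"] * 60 + ["B"] * 240)
        g = build_neighbor_graph(pts, method="knn", parameter=6)
        res = {r.type_pair: r for r in estimate_colocalization(g, types, n_perm=500, seed=5)}
        aa = res[("A", "A")]
        assert aa.enrichment > 0
        assert aa.p_value < 0.05

    def test_zero_observed_pair_finite(self):
        # A and B fully separated: observed A-B adjacency is 0, enrichment
        # must stay finite through the pseudo-count
        pts = np.vstack(
            [np.random.default_rng(6).random((50, 2)) * 0.3,
             np.random.default_rng(7).random((50, 2)) * 0.3 + 0.7]
        )
        types = np.array(["A"] * 50 + ["B"] * 50)
        g = build_neighbor_graph(pts, method="knn", parameter=4)
        res = {r.type_pair: r for r in estimate_colocalization(g, types, n_perm=300, seed=8)}
        ab = res[("A", "B")]
        assert ab.observed == 0
        assert np.isfinite(ab.enrichment) and ab.enrichment < 0


class TestInflation:
    @pytest.mark.parametrize(
        "strengths,eta,nu,expected",
        [
            ([0.0], 2.0, 0.0, 2.0),
            ([3.0], 2.0, 0.0, 8.0),
            ([1.0], 1.0, 1.0, 4.0),
        ],
    )
    def test_formula(self, strengths, eta, nu, expected):
        specs = [ColocalizationSpec(("A", "A"), s) for s in strengths]
        assert compute_inflation_ratio(specs, eta=eta, nu=nu) == pytest.approx(expected)

    def test_empty_specs_default(self):
        assert compute_inflation_ratio([], eta=1.5, nu=0.0) == pytest.approx(1.5)

    def test_clamped_at_one_with_warning(self):
        with pytest.warns(UserWarning):
            lam = compute_inflation_ratio([ColocalizationSpec(("A", "A"), 0.0)], eta=0.5)
        assert lam == 1.0

    def test_eta_must_be_positive(self):
        with pytest.raises(ValueError):
            compute_inflation_ratio([], eta=0.0)


def _nearest_cross_distance(pool, t_from, t_to):
    a = pool.coordinates[pool.cell_types == t_from]
    b = pool.coordinates[pool.cell_types == t_to]
    d = np.linalg.norm(a[:, None] - b[None, :], axis=2)
    if t_from == t_to:
        np.fill_diagonal(d, np.inf)
    return d.min(axis=1).mean()


def _selected_map(strength, seed, unit_window, n_each=150):
    specs = [ColocalizationSpec(("A", "B"), strength)] if strength != 0 else []
    lam = compute_inflation_ratio(specs) if specs else 2.0
    pool = allocate_uniform(
        unit_window, {"A": int(lam * n_each) + 1, "B": int(lam * n_each) + 1}, seed=seed
    )
    return select_cells_with_cci(
        pool, specs, {"A": n_each, "B": n_each}, neighbor_param=8, seed=seed + 1
    )


class TestSelection:
    def test_no_specs_counts_exact(self, unit_window):
        pool = allocate_uniform(unit_window, {"A": 300, "B": 200}, seed=0)
        sel = select_cells_with_cci(pool, [], {"A": 100, "B": 50}, seed=1)
        assert (sel.cell_types == "A").sum() == 100
        assert (sel.cell_types == "B").sum() == 50

    def test_pool_too_small_rejected(self, unit_window):
        pool = allocate_uniform(unit_window, {"A": 10}, seed=0)
        with pytest.raises(ValueError):
            select_cells_with_cci(pool, [], {"A": 20}, seed=1)

    def test_attraction_reduces_cross_type_distance(self, unit_window):
        d_attr, d_none = [], []
        for seed in range(10):
            d_attr.append(_nearest_cross_distance(_selected_map(3.0, 100 + seed, unit_window), "A", "B"))
            d_none.append(_nearest_cross_distance(_selected_map(0.0, 100 + seed, unit_window), "A", "B"))
        assert stats.mannwhitneyu(d_attr, d_none, alternative="less").pvalue < 0.01

    def test_inhibition_increases_cross_type_distance(self, unit_window):
        d_inh, d_none = [], []
        for seed in range(10):
            d_inh.append(_nearest_cross_distance(_selected_map(-3.0, 200 + seed, unit_window), "A", "B"))
            d_none.append(_nearest_cross_distance(_selected_map(0.0, 200 + seed, unit_window), "A", "B"))
        assert stats.mannwhitneyu(d_inh, d_none, alternative="greater").pvalue < 0.01
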