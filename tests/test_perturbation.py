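"""Delta accumulation, count updates, and CCI-effect estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccisim import (
    PerturbationSpec,
    accumulate_delta,
    apply_delta,
    build_neighbor_graph,
    estimate_gene_pair_cci,
    estimate_spatial_dependence,
    generate_reference,
)
from ccisim.fixtures import _default_truth


def _grid_cells(n=100, types=("A", "B"), seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "cell_type": rng.choice(types, size=n),
            "x": rng.random(n),
            "y": rng.random(n),
            "region": np.repeat(["r1", "r2"], n // 2),
        }
    )


class TestAccumulateDelta:
    def test_empty_specs_all_zero(self):
        cells = _grid_cells()
        d = accumulate_delta(cells, [], n_genes=10)
        assert not d.values.any()

    def test_regional_deterministic_entries(self):
        cells = _grid_cells()
        spec = PerturbationSpec(
            kind="regional", perturbed_type="A", region="r1",
            genes=(0, 1), effect_mean=0.7, effect_sd=0.0,
        )
        d = accumulate_delta(cells, [spec], n_genes=10, gene_names=list(range(10)))
        target = ((cells.cell_type == "A") & (cells.region == "r1")).to_numpy()
        assert np.all(d.values[target][:, [0, 1]] == 0.7)
        mask = np.zeros_like(d.values, dtype=bool)
        mask[np.ix_(np.flatnonzero(target), [0, 1])] = True
        assert not d.values[~mask].any()

    def test_overlapping_specs_additive(self):
        cells = _grid_cells()
        mk = lambda mu: PerturbationSpec(
            kind="regional", perturbed_type="A", region=None, genes=(3,), effect_mean=mu, effect_sd=0.0
        )
        d = accumulate_delta(cells, [mk(0.3), mk(0.4)], n_genes=5, gene_names=list(range(5)))
        target = (cells.cell_type == "A").to_numpy()
        assert d.values[target][:, 3] == pytest.approx(0.7)

    def test_unknown_names_rejected_before_mutation(self):
        cells = _grid_cells()
        bad = PerturbationSpec(
            kind="regional", perturbed_type="Z", genes=(0,), effect_mean=0.5
        )
        with pytest.raises(ValueError):
            accumulate_delta(cells, [bad], n_genes=5, gene_names=list(range(5)))

    def test_spatial_dependence_only_hits_qualifying_cells(self):
        cells = pd.DataFrame(
            {
                "cell_type": ["A", "B", "B"],
                "x": [0.0, 0.01, 0.9],
                "y": [0.0, 0.0, 0.9],
                "region": ["r", "r", "r"],
            }
        )
        spec = PerturbationSpec(
            kind="spatial_dependence", perturbed_type="B", neighbor_type="A",
            distance_threshold=0.05, genes=(0,), effect_mean=1.0, effect_sd=0.0,
        )
        d = accumulate_delta(cells, [spec], n_genes=2, gene_names=[0, 1])
        assert d.values[1, 0] == 1.0  # B next to A
        assert d.values[2, 0] == 0.0  # far-away B untouched
        assert not d.values[:, 1].any()

    def test_bidirectional_pair_shares_draw(self):
        cells = pd.DataFrame(
            {
                "cell_type": ["A", "B"],
                "x": [0.0, 0.01],
                "y": [0.0, 0.0],
            }
        )
        spec = PerturbationSpec(
            kind="gene_pair", perturbed_type="A", neighbor_type="B",
            distance_threshold=0.05, gene_pair=("gm", "gn"),
            bidirectional=True, effect_mean=0.5, effect_sd=0.3,
        )
        d = accumulate_delta(cells, [spec], n_genes=2, gene_names=["gm", "gn"], seed=1)
        assert d.values[0, 0] != 0.0
        assert d.values[1, 1] == d.values[0, 0]  # the SAME drawn effect

    def test_provenance_covers_every_nonzero_entry(self):
        cells = _grid_cells(n=60, seed=2)
        specs = [
            PerturbationSpec(kind="regional", perturbed_type="A", region="r1",
                             gene_fraction=0.3, effect_mean=0.5, effect_sd=0.1),
            PerturbationSpec(kind="spatial_dependence", perturbed_type="B", neighbor_type="A",
                             distance_threshold=0.2, gene_fraction=0.2, effect_mean=0.4),
        ]
        d = accumulate_delta(cells, specs, n_genes=10, gene_names=list(range(10)), seed=3)
        covered = np.zeros_like(d.values, dtype=bool)
        for rec in d.provenance:
            covered[np.ix_(rec["cells"], rec["genes"])] = True
        assert np.all(covered[d.values != 0])


class TestApplyDelta:
    def test_zero_delta_is_identity(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5, size=(20, 30))
        out = apply_delta(counts, np.zeros((30, 20)))
        assert np.array_equal(out, counts)

    def test_zero_counts_stay_zero_under_negative_delta(self):
        counts = np.zeros((2, 3), dtype=int)
        out = apply_delta(counts, np.full((3, 2), -1.5))
        assert np.all(out == 0)

    def test_hand_computed_update(self):
        # round(expm1(log1p(10) + 0.5)) = round(11 * e^0.5 - 1) = 17
        counts = np.array([[10]])
        out = apply_delta(counts, np.array([[0.5]]))
        assert out[0, 0] == 17

    def test_cap_max_bounds_extremes(self):
        counts = np.array([[1, 2, 3, 100]])
        out = apply_delta(counts, np.full((4, 1), 5.0), cap_max=True)
        cap = max(5 * np.quantile(counts, 0.975), counts.max())
        assert out.max() <= np.floor(cap + 0.5)

    def test_match_depth_restores_total(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(5, size=(50, 80))
        delta = rng.normal(0.3, 0.2, size=(80, 50))
        out = apply_delta(counts, delta, match_depth=True)
        assert abs(out.sum() - counts.sum()) / counts.sum() < 1e-3


def _planted_bundle(mu, seed, n_genes=100, sd=0.0):
    """Paired fixture with a spatial-dependence effect on well-expressed genes."""
    rng = np.random.default_rng(seed)
    truth = _default_truth(n_genes, 2, rng)
    means = np.array([m.mean * (1 - m.pi) for m in truth.marginals["typeB"]])
    genes = tuple(np.array(truth.gene_names)[np.argsort(-means)[:20]])
    truth.perturbation_specs = [
        PerturbationSpec(
            kind="spatial_dependence", perturbed_type="typeB", neighbor_type="typeA",
            distance_threshold=0.06, genes=genes, effect_mean=mu, effect_sd=sd,
        )
    ]
    return generate_reference("paired", n_cells=500, n_genes=n_genes, n_types=2,
                              truth=truth, seed=seed)


class TestEstimateSpatialDependence:
    def test_null_centered_and_uniform(self):
        bundle, _ = generate_reference("paired", n_cells=400, n_genes=80, n_types=2, seed=20)
        g = build_neighbor_graph(bundle.cells[["x", "y"]].to_numpy(), "distance", 0.06)
        df = estimate_spatial_dependence(
            bundle.counts.to_numpy(), bundle.cells, g, "typeA", "typeB",
            gene_names=bundle.gene_names, n_perm=300, seed=21,
        )
        assert abs(df.log2fc.median()) < 0.1
        assert stats.kstest(df.p_value, "uniform").pvalue > 0.01

    def test_planted_effect_recovered_in_log2(self):
        bundle, truth = _planted_bundle(0.5, seed=22)
        g = build_neighbor_graph(bundle.cells[["x", "y"]].to_numpy(), "distance", 0.06)
        df = estimate_spatial_dependence(
            bundle.counts.to_numpy(), bundle.cells, g, "typeA", "typeB",
            gene_names=bundle.gene_names, n_perm=300, seed=23,
        )
        planted = truth.delta_provenance[0]["genes"]
        assert df.iloc[planted].log2fc.median() == pytest.approx(0.5 / np.log(2), abs=0.15)

    def test_tiny_group_skipped(self):
        cells = pd.DataFrame(
            {"cell_type": ["A", "B", "B", "B"], "x": [0.0, 0.01, 0.5, 0.6], "y": [0.0] * 4}
        )
        g = build_neighbor_graph(cells[["x", "y"]].to_numpy(), "distance", 0.05)
        counts = np.ones((3, 4))
        df = estimate_spatial_dependence(counts, cells, g, "A", "B", n_perm=50, seed=24)
        assert df.empty


class TestEstimateGenePair:
    def test_empty_pair_list(self):
        bundle, _ = generate_reference("paired", n_cells=200, n_genes=20, n_types=2, seed=25)
        g = build_neighbor_graph(bundle.cells[["x", "y"]].to_numpy(), "distance", 0.08)
        df = estimate_gene_pair_cci(
            bundle.counts.to_numpy(), bundle.cells, g, pd.DataFrame(columns=["ligand", "receptor"]),
            "typeA", "typeB", gene_names=bundle.gene_names, seed=26,
        )
        assert df.empty

    def test_null_pairs_centered(self):
        bundle, _ = generate_reference("paired", n_cells=300, n_genes=40, n_types=2, seed=27)
        pairs = pd.DataFrame({"ligand": bundle.gene_names[:8], "receptor": bundle.gene_names[8:16]})
        g = build_neighbor_graph(bundle.cells[["x", "y"]].to_numpy(), "distance", 0.08)
        df = estimate_gene_pair_cci(
            bundle.counts.to_numpy(), bundle.cells, g, pairs, "typeA", "typeB",
            gene_names=bundle.gene_names, n_perm=300, seed=28,
        )
        assert df.log2fc_product.abs().median() < 0.2

    def test_missing_gene_skipped(self):
        bundle, _ = generate_reference("paired", n_cells=200, n_genes=20, n_types=2, seed=29)
        pairs = pd.DataFrame({"ligand": ["nope"], "receptor": [bundle.gene_names[0]]})
        g = build_neighbor_graph(bundle.cells[["x", "y"]].to_numpy(), "distance", 0.08)
        df = estimate_gene_pair_cci(
            bundle.counts.to_numpy(), bundle.cells, g, pairs, "typeA", "typeB",
            gene_names=bundle.gene_names, n_perm=50, seed=30,
        )
        assert df.empty
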