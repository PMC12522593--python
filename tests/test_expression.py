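"""ZINB marginals, copula correlation, count drawing."""

import numpy as np
import pandas as pd
import pytest

from ccisim import (
    CellTypeExpressionModel,
    GeneMarginal,
    draw_counts,
    fit_copula_correlation,
    fit_expression_model,
    fit_marginal,
    subsample_cells,
)


def _draw(marg, n, seed, **kw):
    model = CellTypeExpressionModel("t", ["g"], [marg])
    return draw_counts(model, n, use_correlation=False, seed=seed, **kw)[0]


class TestFitMarginal:
    def test_all_zero_gene_degenerate(self):
        m = fit_marginal(np.zeros(100, dtype=int))
        assert m.pi == 1.0
        assert np.all(_draw(m, 50, seed=0) == 0)

    def test_zinb_parameter_recovery(self):
        truth = GeneMarginal(pi=0.3, mean=5.0, dispersion=2.0)
        y = _draw(truth, 5000, seed=1)
        fit = fit_marginal(y)
        assert fit.pi == pytest.approx(0.3, rel=0.10)
        assert fit.mean == pytest.approx(5.0, rel=0.10)
        assert fit.dispersion == pytest.approx(2.0, rel=0.10)
        assert fit.family == "zinb"

    def test_poisson_data_falls_back(self):
        y = np.random.default_rng(2).poisson(3.0, size=5000)
        fit = fit_marginal(y)
        assert fit.family in ("poisson", "zip")
        assert fit.mean == pytest.approx(3.0, rel=0.05)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            fit_marginal(np.array([]))

    def test_real_valued_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_marginal(np.array([0.0, 1.5, 2.0]))


class TestCopula:
    def _pair_model(self, rho):
        sigma = np.array([[1.0, rho], [rho, 1.0]])
        margs = [GeneMarginal(0.2, 5.0, 2.0), GeneMarginal(0.1, 3.0, 1.5)]
        return CellTypeExpressionModel("t", ["a", "b"], margs, sigma=sigma), margs

    def test_independent_genes_near_zero(self):
        margs = [GeneMarginal(0.1, 4.0, 2.0) for _ in range(4)]
        model = CellTypeExpressionModel("t", list("abcd"), margs)
        Y = draw_counts(model, 2000, use_correlation=False, seed=3)
        R = fit_copula_correlation(Y, margs, seed=4)
        off = R[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1

    @pytest.mark.parametrize("rho", [0.3, 0.6, 0.9])
    def test_latent_correlation_recovery(self, rho):
        model, margs = self._pair_model(rho)
        Y = draw_counts(model, 2000, seed=int(rho * 10))
        R = fit_copula_correlation(Y, margs, seed=5)
        assert R[0, 1] == pytest.approx(rho, abs=0.1)

    def test_estimate_is_valid_correlation_matrix(self, paired_bundle):
        bundle, _ = paired_bundle
        sub = bundle.counts.to_numpy()[:10, :]
        margs = [fit_marginal(sub[g]) for g in range(10)]
        R = fit_copula_correlation(sub, margs, seed=6)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)
        assert np.linalg.eigvalsh(R).min() >= -1e-8

    def test_constant_gene_identity_row(self):
        margs = [GeneMarginal(0.0, 3.0, 2.0), GeneMarginal(0.0, 3.0, 2.0)]
        Y = np.vstack([np.full(50, 2), np.random.default_rng(7).poisson(3, 50)])
        R = fit_copula_correlation(Y, margs, seed=8)
        assert R[0, 1] == 0.0


class TestSubsample:
    def test_small_stratum_kept_whole(self):
        cells = pd.DataFrame({"cell_type": ["A"] * 100})
        assert len(subsample_cells(cells, cap=2500, seed=0)) == 100

    def test_large_stratum_capped(self):
        cells = pd.DataFrame({"cell_type": ["A"] * 6000, "region": ["r1"] * 6000})
        assert len(subsample_cells(cells, cap=2500, seed=1)) == 2500

    def test_stratified_by_type_and_region(self):
        cells = pd.DataFrame(
            {"cell_type": ["A"] * 30 + ["B"] * 30, "region": (["r1"] * 15 + ["r2"] * 15) * 2}
        )
        idx = subsample_cells(cells, cap=10, seed=2)
        picked = cells.iloc[idx]
        assert picked.groupby(["cell_type", "region"]).size().eq(10).all()

    def test_reproducible(self):
        cells = pd.DataFrame({"cell_type": ["A"] * 100})
        a = subsample_cells(cells, cap=40, seed=3)
        b = subsample_cells(cells, cap=40, seed=3)
        assert np.array_equal(a, b)


class TestDrawCounts:
    def test_moments_match_marginal(self):
        truth = GeneMarginal(pi=0.25, mean=6.0, dispersion=2.5)
        y = _draw(truth, 5000, seed=9)
        mom = truth.theoretical_moments()
        n = 5000
        se_mean = np.sqrt(mom["var"] / n)
        assert abs(y.mean() - mom["mean"]) < 3 * se_mean
        se_zero = np.sqrt(mom["zero_fraction"] * (1 - mom["zero_fraction"]) / n)
        assert abs(np.mean(y == 0) - mom["zero_fraction"]) < 3 * se_zero

    def test_depth_factor_doubles_totals(self):
        margs = [GeneMarginal(0.1, m, 2.0) for m in (2.0, 5.0, 10.0)]
        model = CellTypeExpressionModel("t", list("abc"), margs)
        y1 = draw_counts(model, 5000, depth_factor=1.0, use_correlation=False, seed=10)
        y2 = draw_counts(model, 5000, depth_factor=2.0, use_correlation=False, seed=11)
        assert 1.9 <= y2.sum() / y1.sum() <= 2.1

    def test_high_latent_correlation_visible_in_counts(self):
        from scipy.stats import spearmanr

        sigma = np.array([[1.0, 0.8], [0.8, 1.0]])
        margs = [GeneMarginal(0.1, 5.0, 2.0), GeneMarginal(0.1, 5.0, 2.0)]
        model = CellTypeExpressionModel("t", ["a", "b"], margs, sigma=sigma)
        Y = draw_counts(model, 5000, seed=12)
        assert spearmanr(Y[0], Y[1]).statistic > 0.5

    def test_marginals_preserved_under_strong_correlation(self):
        # the copula must not distort the marginals, whatever sigma is
        rho = 0.9
        sigma = np.full((3, 3), rho)
        np.fill_diagonal(sigma, 1.0)
        margs = [GeneMarginal(0.3, 4.0, 1.5), GeneMarginal(0.1, 8.0, 3.0), GeneMarginal(0.2, 1.5, 1.0)]
        model = CellTypeExpressionModel("t", list("abc"), margs, sigma=sigma)
        Y = draw_counts(model, 5000, seed=13)
        for g, m in enumerate(margs):
            mom = m.theoretical_moments()
            assert abs(Y[g].mean() - mom["mean"]) < 3 * np.sqrt(mom["var"] / 5000)
            se0 = np.sqrt(mom["zero_fraction"] * (1 - mom["zero_fraction"]) / 5000)
            assert abs(np.mean(Y[g] == 0) - mom["zero_fraction"]) < 3 * se0

    def test_zero_cells(self):
        model = CellTypeExpressionModel("t", ["g"], [GeneMarginal(0.1, 2.0, 1.0)])
        assert draw_counts(model, 0, seed=14).shape == (1, 0)


class TestFitExpressionModel:
    def test_fit_and_redraw_roundtrip(self, paired_bundle):
        bundle, truth = paired_bundle
        ct = truth.cell_types[0]
        idx = np.flatnonzero(bundle.cells["cell_type"] == ct)
        sub = bundle.counts.to_numpy()[:15, idx]
        model = fit_expression_model(sub, bundle.gene_names[:15], cell_type=ct, seed=15)
        assert len(model.marginals) == 15
        Y = draw_counts(model, 200, seed=16)
        assert Y.shape == (15, 200)

    def test_serialization_round_trip(self, tmp_path, paired_bundle):
        bundle, _ = paired_bundle
        sub = bundle.counts.to_numpy()[:5, :]
        model = fit_expression_model(sub, bundle.gene_names[:5], cell_type="typeA", seed=17)
        model.save(tmp_path / "m")
        back = CellTypeExpressionModel.load(tmp_path / "m")
        assert [m.mean for m in back.marginals] == pytest.approx([m.mean for m in model.marginals])
        assert np.allclose(back.sigma, model.sigma)
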