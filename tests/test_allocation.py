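"""Poisson point-process fitting, M-H sampling, uniform allocation, overlap removal."""

import numpy as np
import pytest
from scipy import stats
from shapely.geometry import box

from ccisim import (
    IntensityModel,
    SpatialWindow,
    allocate_uniform,
    fit_intensity,
    partition_unit_square,
    remove_overlaps,
    sample_intensity_mh,
)


def linear_trend_model(beta1: float, unit_window) -> IntensityModel:
    """log lambda = log(1000) + beta1 * x on the unit square."""
    coef = np.zeros(6)
    coef[0] = np.log(1000.0)
    coef[1] = beta1
    return IntensityModel(
        cell_type="t", degree=2, coefficients=coef, window=unit_window,
        max_log_intensity=coef[0] + max(beta1, 0.0),
    )


class TestFitIntensity:
    def test_homogeneous_recovers_flat_surface(self, unit_window):
        rng = np.random.default_rng(0)
        pts = rng.random((500, 2))
        m = fit_intensity(pts, unit_window)
        # fitted intensity should be nearly constant: log-range over the
        # window small relative to the homogeneous level log(500)
        gx = np.linspace(0.05, 0.95, 25)
        XX, YY = np.meshgrid(gx, gx)
        ll = m.log_intensity(XX.ravel(), YY.ravel())
        assert ll.max() - ll.min() < 1.0
        assert np.median(ll) == pytest.approx(np.log(500), abs=0.4)

    def test_linear_trend_recovery(self, unit_window):
        # raw polynomial coefficients are collinear on [0, 1]; the
        # identifiable quantity is the fitted log-intensity slope in x
        model = linear_trend_model(2.0, unit_window)
        pts = sample_intensity_mh(model, 500, iterations=100_000, seed=1)
        fit = fit_intensity(pts, unit_window, degree=2)
        gx = np.linspace(0.02, 0.98, 50)
        slope = np.polyfit(gx, fit.log_intensity(gx, np.full(50, 0.5)), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.5)

    def test_small_type_gets_quadratic_surface(self, unit_window):
        pts = np.random.default_rng(2).random((8, 2))
        m = fit_intensity(pts, unit_window)
        assert m.degree == 2
        assert len(m.coefficients) == 6

    def test_eleven_cells_get_cubic_surface(self, unit_window):
        pts = np.random.default_rng(3).random((11, 2))
        m = fit_intensity(pts, unit_window)
        assert m.degree == 3
        assert len(m.coefficients) == 10

    def test_json_round_trip(self, unit_window):
        pts = np.random.default_rng(4).random((50, 2))
        m = fit_intensity(pts, unit_window)
        m2 = IntensityModel.from_json(m.to_json())
        assert np.allclose(m.coefficients, m2.coefficients)
        assert m2.degree == m.degree


class TestSampleIntensityMH:
    def test_constant_intensity_is_uniform(self, unit_window):
        model = linear_trend_model(0.0, unit_window)
        pts = sample_intensity_mh(model, 1000, iterations=100_000, seed=5)
        assert len(pts) == 1000
        # quadrat chi-square uniformity on a 5x5 grid
        ix = np.minimum((pts[:, 0] * 5).astype(int), 4)
        iy = np.minimum((pts[:, 1] * 5).astype(int), 4)
        counts = np.bincount(ix * 5 + iy, minlength=25)
        chi2 = ((counts - 40.0) ** 2 / 40.0).sum()
        assert stats.chi2.sf(chi2, df=24) > 0.01

    def test_linear_trend_matches_integrated_intensity(self, unit_window):
        model = linear_trend_model(3.0, unit_window)
        pts = sample_intensity_mh(model, 2000, iterations=200_000, seed=6)
        edges = np.linspace(0, 1, 11)
        counts = np.histogram(pts[:, 0], bins=edges)[0]
        integral = np.diff(np.exp(3.0 * edges)) / 3.0
        r = stats.pearsonr(counts, integral)[0]
        assert r >= 0.9

    def test_zero_target_gives_empty_set(self, unit_window):
        model = linear_trend_model(0.0, unit_window)
        assert sample_intensity_mh(model, 0, seed=0).shape == (0, 2)

    def test_all_points_inside_window(self):
        tri_window = SpatialWindow(box(0.2, 0.3, 0.7, 0.9))
        coef = np.zeros(6)
        coef[0] = np.log(500.0)
        model = IntensityModel("t", 2, coef, tri_window, coef[0])
        pts = sample_intensity_mh(model, 500, iterations=50_000, seed=7)
        assert tri_window.contains(pts[:, 0], pts[:, 1]).all()


class TestAllocateUniform:
    def test_counts_respected_single_window(self, unit_window):
        pool = allocate_uniform(unit_window, {"A": 100}, seed=0)
        assert len(pool) == 100
        assert set(pool.cell_types) == {"A"}

    def test_per_region_counts_and_labels(self):
        part = partition_unit_square(K=2, B=10, seed=1)
        pool = allocate_uniform(part, {1: {"A": 50}, 2: {"B": 50}}, seed=2)
        for region, ct in ((1, "A"), (2, "B")):
            sel = pool.regions == region
            assert sel.sum() == 50
            assert set(pool.cell_types[sel]) == {ct}
            # placed inside the region's pixels
            assert np.all(part.region_of(pool.coordinates[sel, 0], pool.coordinates[sel, 1]) == region)

    def test_zero_counts_give_empty_pool(self, unit_window):
        pool = allocate_uniform(unit_window, {"A": 0}, seed=3)
        assert len(pool) == 0


class TestRemoveOverlaps:
    def test_coincident_pair_keeps_one(self):
        pts = np.array([[0.5, 0.5], [0.5, 0.5]])
        keep = remove_overlaps(pts, min_distance=0.01, seed=0)
        assert len(keep) == 1

    def test_zero_min_distance_is_identity(self):
        pts = np.random.default_rng(1).random((50, 2))
        assert len(remove_overlaps(pts, 0.0)) == 50

    def test_lattice_conflicts_resolved(self):
        g = np.linspace(0, 1, 10)
        XX, YY = np.meshgrid(g, g)
        pts = np.column_stack([XX.ravel(), YY.ravel()])
        min_d = 0.15  # lattice spacing ~0.111 < min_d
        keep = remove_overlaps(pts, min_d, seed=2)
        kept = pts[keep]
        d = np.linalg.norm(kept[:, None] - kept[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= min_d
        # every removed point has a kept point within min_d
        removed = np.setdiff1d(np.arange(len(pts)), keep)
        dr = np.linalg.norm(pts[removed][:, None] - kept[None, :], axis=2)
        assert (dr.min(axis=1) < min_d).all()

    def test_idempotent(self):
        pts = np.random.default_rng(3).random((200, 2))
        keep = remove_overlaps(pts, 0.05, seed=4)
        again = remove_overlaps(pts[keep], 0.05, seed=5)
        assert len(again) == len(keep)
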