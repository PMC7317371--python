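import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from fieldscape.landscape import (
    cluster_journal_topics, density_grid, embed_2d, field_boundary,
    grid_extent, hellinger_distance, hellinger_matrix, period_landscapes,
    weighted_density,
)


class TestHellinger:
    def test_identical_distributions(self):
        assert hellinger_distance([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_disjoint_supports(self):
        assert hellinger_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        d = hellinger_distance([0.5, 0.5], [0.9, 0.1])
        assert d == pytest.approx(0.32492, abs=1e-5)

    def test_unnormalized_input_fatal(self):
        with pytest.raises(ValueError):
            hellinger_distance([0.5, 0.6], [0.5, 0.5])
        with pytest.raises(ValueError):
            hellinger_distance([-0.1, 1.1], [0.5, 0.5])

    def test_metric_properties_on_random_vectors(self):
        # symmetry, identity, triangle inequality over many random draws
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p, q, r = rng.dirichlet(np.ones(5), size=3)
            dpq = hellinger_distance(p, q)
            assert dpq == pytest.approx(hellinger_distance(q, p))
            assert 0.0 <= dpq <= 1.0
            assert dpq <= hellinger_distance(p, r) + hellinger_distance(r, q) + 1e-12

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(1)
        theta = rng.dirichlet(np.ones(4), size=6)
        M = hellinger_matrix(theta)
        for i in range(6):
            for j in range(6):
                assert M[i, j] == pytest.approx(
                    hellinger_distance(theta[i], theta[j]), abs=1e-7)


@pytest.fixture(scope="module")
def clustered_embedding():
    """θ with three well-separated planted clusters plus its embedding."""
    rng = np.random.default_rng(5)
    blocks = []
    labels = []
    for c in range(3):
        alpha = np.full(9, 0.05)
        alpha[3 * c:3 * c + 3] = 5.0
        blocks.append(rng.dirichlet(alpha, size=40))
        labels += [c] * 40
    theta = np.vstack(blocks)
    coords = embed_2d(theta, perplexity=15, seed=0, n_iter=500)
    return theta, np.asarray(labels), coords


class TestEmbed2D:
    def test_planted_clusters_stay_separated(self, clustered_embedding):
        _, labels, coords = clustered_embedding
        assert silhouette_score(coords, labels) > 0.5

    def test_duplicated_points_land_together(self, clustered_embedding):
        theta, _, _ = clustered_embedding
        dup = np.vstack([theta, theta[:1]])
        coords = embed_2d(dup, perplexity=15, seed=1, n_iter=400)
        extent = coords.max(axis=0) - coords.min(axis=0)
        gap = np.linalg.norm(coords[0] - coords[-1])
        assert gap < 0.01 * np.linalg.norm(extent)

    def test_deterministic_under_seed(self, clustered_embedding):
        theta, _, _ = clustered_embedding
        a = embed_2d(theta[:60], perplexity=10, seed=3, n_iter=300)
        b = embed_2d(theta[:60], perplexity=10, seed=3, n_iter=300)
        assert np.array_equal(a, b)

    def test_perplexity_infeasible(self):
        with pytest.raises(ValueError, match="perplexity"):
            embed_2d(np.full((10, 3), 1 / 3), perplexity=30)


class TestDensityGrid:
    def test_single_point_peaks_at_its_cell(self):
        coords = np.array([[0.0, 0.0], [10.0, 10.0]])
        with pytest.warns(UserWarning, match="bandwidth"):
            grid = density_grid(coords, subset=[True, False], G=50)
        iy, ix = np.unravel_index(grid.density.argmax(), grid.density.shape)
        xs, ys = grid.cell_centers()
        assert abs(xs[ix] - 0.0) < (xs[1] - xs[0]) * 2
        assert abs(ys[iy] - 0.0) < (ys[1] - ys[0]) * 2

    def test_brute_force_kernel_sum_oracle(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(500, 2))
        grid = density_grid(coords, G=40, bandwidth=(0.3, 0.4))
        xs, ys = grid.cell_centers()
        hx, hy = grid.bandwidth
        direct = np.zeros_like(grid.density)
        for iy in range(40):       # O(N G^2) double loop
            for ix in range(40):
                z = ((xs[ix] - coords[:, 0]) / hx) ** 2 + \
                    ((ys[iy] - coords[:, 1]) / hy) ** 2
                direct[iy, ix] = np.sum(np.exp(-0.5 * z)) / \
                    (500 * 2 * np.pi * hx * hy)
        direct /= direct.sum() * grid.cell_area
        rel = np.abs(grid.density - direct) / direct.max()
        assert rel.max() < 1e-8

    def test_normalizes_to_one_over_grid(self):
        rng = np.random.default_rng(3)
        grid = density_grid(rng.normal(size=(200, 2)), G=64)
        assert grid.density.sum() * grid.cell_area == pytest.approx(1.0, abs=1e-6)

    def test_two_equal_clusters_two_equal_peaks(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.3, size=(250, 2)) + [-3, 0]
        b = rng.normal(0, 0.3, size=(250, 2)) + [3, 0]
        grid = density_grid(np.vstack([a, b]), G=80, bandwidth=(0.3, 0.3))
        half = grid.density.shape[1] // 2
        left, right = grid.density[:, :half].max(), grid.density[:, half:].max()
        assert 0.8 < left / right < 1.25


class TestWeightedDensity:
    def test_uniform_weights_match_unweighted(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(100, 2))
        g0 = density_grid(coords, G=32, bandwidth=(0.5, 0.5))
        g1 = weighted_density(coords, np.full(100, 0.37), bandwidth=(0.5, 0.5),
                              G=32)
        assert np.abs(g0.density - g1.density).max() < 1e-10 * g0.density.max()

    def test_single_positive_weight_reduces_to_one_kernel(self):
        coords = np.array([[0.0, 0.0], [5.0, 5.0]])
        w = np.array([0.0, 1.0])
        g = weighted_density(coords, w, bandwidth=(0.4, 0.4), G=32)
        only = density_grid(coords, subset=[False, True], bandwidth=(0.4, 0.4),
                            G=32, extent=g.extent)
        assert np.allclose(g.density, only.density)

    def test_all_zero_weights_fatal(self):
        with pytest.raises(ValueError, match="zero"):
            weighted_density(np.zeros((3, 2)), np.zeros(3))


class TestFieldBoundary:
    def _gaussian_grids(self, sep=2.0, n=400, seed=6):
        rng = np.random.default_rng(seed)
        eco = rng.normal(size=(n, 2)) + [-sep, 0]
        cons = rng.normal(size=(n, 2)) + [sep, 0]
        coords = np.vstack([eco, cons])
        extent = grid_extent(coords)
        g_eco = density_grid(coords, subset=np.r_[np.ones(n), np.zeros(n)] > 0,
                             G=100, extent=extent, bandwidth=(0.5, 0.5))
        g_cons = density_grid(coords, subset=np.r_[np.zeros(n), np.ones(n)] > 0,
                              G=100, extent=extent, bandwidth=(0.5, 0.5))
        return g_eco, g_cons

    def test_identical_grids_all_cells_above_floor(self):
        g_eco, _ = self._gaussian_grids()
        boundary = field_boundary(g_eco, g_eco)
        total = 2 * g_eco.density
        expected = int((total >= 0.05 * total.max()).sum())
        assert len(boundary) == expected

    def test_boundary_tracks_the_perpendicular_bisector(self):
        g_eco, g_cons = self._gaussian_grids(sep=2.0)
        boundary = field_boundary(g_eco, g_cons)
        assert len(boundary) > 0
        assert np.abs(boundary["x"]).mean() < 0.2

    def test_disjoint_supports_empty_boundary(self):
        g_eco, g_cons = self._gaussian_grids(sep=12.0)
        with pytest.warns(UserWarning, match="no boundary"):
            boundary = field_boundary(g_eco, g_cons)
        assert boundary.empty

    def test_lattice_mismatch_fatal(self):
        g_eco, _ = self._gaussian_grids()
        other = density_grid(np.random.default_rng(0).normal(size=(50, 2)), G=64)
        with pytest.raises(ValueError):
            field_boundary(g_eco, other)


class TestPeriodLandscapes:
    def test_period_bounds_inclusive(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(60, 2))
        labels = np.array(["ecology", "ecology",
                           "conservation", "conservation"] * 15)
        years = np.array([2004, 2005] * 30)
        grids = period_landscapes(coords, labels, years, G=32)
        labels_seen = {g.label for g in grids}
        assert "2000-2004:ecology" in labels_seen      # 2004 -> first period
        assert "2005-2009:ecology" in labels_seen      # 2005 -> second period
        assert not any(lab.startswith("2010") for lab in labels_seen)

    def test_single_period_corpus(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(40, 2))
        labels = np.array(["ecology"] * 20 + ["conservation"] * 20)
        years = np.full(40, 2012)
        grids = period_landscapes(coords, labels, years, G=32)
        assert len(grids) == 2

    def test_uncovered_year_fatal(self):
        coords = np.zeros((4, 2))
        with pytest.raises(ValueError):
            period_landscapes(coords, ["ecology"] * 4, [1999] * 4)

    def test_same_extent_across_periods(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(80, 2))
        labels = np.array(["ecology", "conservation"] * 40)
        years = np.array([2001, 2008] * 40)
        grids = period_landscapes(coords, labels, years, G=32)
        assert len({g.extent for g in grids}) == 1


class TestJournalClustering:
    def test_same_field_journals_merge_first(self):
        rng = np.random.default_rng(10)
        alpha_a = np.array([5.0, 5.0, 0.2, 0.2])
        alpha_b = np.array([0.2, 0.2, 5.0, 5.0])
        theta = np.vstack([
            rng.dirichlet(alpha_a, 30), rng.dirichlet(alpha_a, 30),
            rng.dirichlet(alpha_b, 30),
        ])
        journals = ["A1"] * 30 + ["A2"] * 30 + ["B1"] * 30
        result = cluster_journal_topics(theta, journals)
        # first merge joins the two same-prior journals
        first = result.row_linkage[0, :2].astype(int)
        names = sorted(result.matrix.index[i] for i in first)
        assert names == ["A1", "A2"]

    def test_single_journal_fatal(self):
        with pytest.raises(ValueError, match="2 journals"):
            cluster_journal_topics(np.full((3, 2), 0.5), ["J"] * 3)

    def test_identical_journals_merge_at_zero_height(self):
        theta = np.tile([0.4, 0.6], (6, 1))
        result = cluster_journal_topics(theta, ["X", "X", "X", "Y", "Y", "Y"])
        assert result.row_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_small_journal_flagged_but_included(self):
        rng = np.random.default_rng(11)
        theta = rng.dirichlet(np.ones(3), size=8)
        journals = ["big"] * 6 + ["tiny"] * 2
        result = cluster_journal_topics(theta, journals)
        assert result.flagged_journals == ["tiny"]
        assert list(result.matrix.index) == ["big", "tiny"]
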