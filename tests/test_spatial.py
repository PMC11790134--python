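import numpy as np
import pytest

from soilcap.spatial import (Grid, VariogramModel, combined_surface,
                             detect_polluted_area, ebk_style,
                             empirical_variogram, fit_variogram, idw,
                             kriging_weights, make_grid, ordinary_kriging,
                             pollution_area_table, study_mask)


def _grf(n, true_range, domain=1000.0, sill=4.0, mean=10.0, seed=0,
         nugget=0.0):
    """One realization of an exponential-covariance Gaussian field."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, domain, (n, 2))
    d = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
    cov = sill * np.exp(-d / true_range) + nugget * np.eye(n)
    L = np.linalg.cholesky(cov + 1e-8 * np.eye(n))
    return coords, mean + L @ rng.standard_normal(n)


@pytest.fixture(scope="module")
def smooth_field():
    return _grf(n=60, true_range=250.0, seed=7)


class TestIDW:
    def test_constant_field_gives_constant_surface(self, smooth_field):
        coords, _ = smooth_field
        grid = make_grid(coords, ncells=30)
        surf = idw(coords, np.full(len(coords), 3.14), grid)
        np.testing.assert_allclose(surf.masked_values(), 3.14)

    def test_exact_at_site_coincident_cell(self):
        grid = Grid(x0=0, y0=0, cell=10, ncols=10, nrows=10)
        coords = np.array([[15.0, 25.0], [75.0, 85.0]])  # exact cell centers
        vals = np.array([1.0, 9.0])
        surf = idw(coords, vals, grid, mask=np.ones((10, 10), bool))
        assert surf.values[2, 1] == pytest.approx(1.0)
        assert surf.values[8, 7] == pytest.approx(9.0)

    def test_matches_brute_force_weighted_mean(self):
        coords = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        vals = np.array([1.0, 5.0, 9.0])
        grid = Grid(x0=0, y0=0, cell=4, ncols=3, nrows=3)
        surf = idw(coords, vals, grid, power=2,
                   mask=np.ones((3, 3), bool))
        for r in range(3):
            for c in range(3):
                p = np.array([grid.xs[c], grid.ys[r]])
                w = 1.0 / np.linalg.norm(coords - p, axis=1) ** 2
                assert surf.values[r, c] == pytest.approx((w @ vals) / w.sum())

    def test_predictions_bounded_by_data(self, smooth_field):
        coords, vals = smooth_field
        surf = idw(coords, vals, make_grid(coords, ncells=40))
        inside = surf.masked_values()
        assert inside.min() >= vals.min() - 1e-9
        assert inside.max() <= vals.max() + 1e-9

    def test_requires_sites(self):
        with pytest.raises(ValueError):
            idw(np.empty((0, 2)), np.empty(0), Grid(0, 0, 1, 4, 4))


class TestVariogram:
    def test_range_recovery_on_synthetic_field(self):
        coords, vals = _grf(n=200, true_range=100.0, seed=3)
        vm = fit_variogram(coords, vals)
        assert abs(vm.range_ - 100.0) / 100.0 < 0.5

    def test_shuffled_field_looks_like_pure_nugget(self):
        coords, vals = _grf(n=150, true_range=300.0, seed=5)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(vals)
        vm = fit_variogram(coords, shuffled)
        # spatial structure destroyed: either nugget ~ sill or tiny range
        structured = (vm.sill - vm.nugget) / max(vm.sill, 1e-12)
        assert structured < 0.5 or vm.range_ < 50.0

    def test_constant_field_zero_sill(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 100, (30, 2))
        vm = fit_variogram(coords, np.full(30, 2.0))
        assert vm.sill == 0.0 and vm.nugget == 0.0

    def test_collinear_geometry_warns_but_fits(self):
        x = np.linspace(0, 100, 30)
        coords = np.column_stack([x, np.zeros_like(x)])
        vals = np.sin(x / 20.0) + 2.0
        with pytest.warns(UserWarning, match="collinear"):
            fit_variogram(coords, vals)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            empirical_variogram(np.array([[0.0, 0], [1, 1], [2, 0]]),
                                np.array([1.0, 2, 3]))


class TestOrdinaryKriging:
    def test_zero_nugget_weights_are_exact_at_a_site(self, smooth_field):
        coords, vals = smooth_field
        vm = VariogramModel("exponential", 0.0, float(vals.var()), 250.0)
        w = kriging_weights(coords, vm, coords[4])
        expected = np.zeros(len(coords))
        expected[4] = 1.0
        np.testing.assert_allclose(w, expected, atol=1e-5)

    def test_constant_field_gives_constant_surface(self, smooth_field):
        coords, _ = smooth_field
        grid = make_grid(coords, ncells=25)
        vm = fit_variogram(coords, np.full(len(coords), 7.0))
        surf = ordinary_kriging(coords, np.full(len(coords), 7.0), grid, vm)
        np.testing.assert_allclose(surf.masked_values(), 7.0)

    def test_pure_nugget_collapses_to_global_mean(self, smooth_field):
        coords, vals = smooth_field
        grid = make_grid(coords, ncells=20)
        vm = VariogramModel("exponential", float(vals.var()),
                            float(vals.var()), 100.0)
        surf = ordinary_kriging(coords, vals, grid, vm)
        np.testing.assert_allclose(surf.masked_values(), vals.mean(), rtol=1e-6)

    def test_four_site_weights_match_hand_solved_system(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0],
                           [100.0, 100.0]])
        vm = VariogramModel("spherical", 0.5, 3.0, 150.0)
        target = np.array([40.0, 30.0])
        w = kriging_weights(coords, vm, target)
        # independent dense solve of the same BLUP system
        K = np.ones((5, 5))
        K[4, 4] = 0.0
        for i in range(4):
            for j in range(4):
                h = np.linalg.norm(coords[i] - coords[j])
                K[i, j] = vm.covariance(np.array(h))
        rhs = np.ones(5)
        for i in range(4):
            rhs[i] = vm.covariance(
                np.array(np.linalg.norm(coords[i] - target)))
        expected = np.linalg.solve(K, rhs)[:4]
        np.testing.assert_allclose(w, expected, atol=1e-8)
        assert w.sum() == pytest.approx(1.0)  # unbiasedness constraint

    def test_duplicate_sites_deduplicated_with_warning(self, smooth_field):
        coords, vals = smooth_field
        coords2 = np.vstack([coords, coords[0]])
        vals2 = np.append(vals, vals[0] + 2.0)
        grid = make_grid(coords, ncells=15)
        vm = fit_variogram(coords, vals)
        with pytest.warns(UserWarning, match="duplicate"):
            ordinary_kriging(coords2, vals2, grid, vm)


class TestEBK:
    def test_single_member_reduces_to_ordinary_kriging(self, smooth_field):
        coords, vals = smooth_field
        grid = make_grid(coords, ncells=20)
        vm = fit_variogram(coords, vals)
        a = ebk_style(coords, vals, grid, K=1, seed=0)
        b = ordinary_kriging(coords, vals, grid, vm)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-10)

    def test_seed_determinism(self, smooth_field):
        coords, vals = smooth_field
        grid = make_grid(coords, ncells=15)
        a = ebk_style(coords, vals, grid, K=8, seed=42)
        b = ebk_style(coords, vals, grid, K=8, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_accuracy_close_to_ordinary_kriging(self):
        # grid-truth comparison: simulate the field at grid nodes + sites,
        # observe the sites, predict the grid, compare RMSE inside the hull
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 1000, (45, 2))
        grid = make_grid(coords, ncells=12)
        centers = grid.centers()
        allpts = np.vstack([coords, centers])
        d = np.linalg.norm(allpts[:, None] - allpts[None], axis=-1)
        cov = 4.0 * np.exp(-d / 250.0)
        L = np.linalg.cholesky(cov + 1e-8 * np.eye(len(allpts)))
        z = 10.0 + L @ rng.standard_normal(len(allpts))
        vals, truth = z[:45], z[45:].reshape(grid.nrows, grid.ncols)
        mask = study_mask(coords, grid)
        vm = fit_variogram(coords, vals)
        ok = ordinary_kriging(coords, vals, grid, vm, mask=mask)
        ebk = ebk_style(coords, vals, grid, K=30, seed=1, mask=mask)
        rmse_ok = np.sqrt(np.mean((ok.values[mask] - truth[mask]) ** 2))
        rmse_ebk = np.sqrt(np.mean((ebk.values[mask] - truth[mask]) ** 2))
        assert rmse_ebk <= 1.1 * rmse_ok


class TestAreaDetection:
    def test_every_site_and_cell_contaminated(self, smooth_field):
        coords, _ = smooth_field
        grid = make_grid(coords, ncells=20)
        vals = np.full(len(coords), 5.0)
        surf = idw(coords, vals, grid)
        site_fr, area_fr = detect_polluted_area(vals, surf, lambda v: v > 1)
        assert (site_fr, area_fr) == (100.0, 100.0)

    def test_no_violations(self, smooth_field):
        coords, _ = smooth_field
        grid = make_grid(coords, ncells=20)
        vals = np.full(len(coords), 0.5)
        surf = idw(coords, vals, grid)
        assert detect_polluted_area(vals, surf, lambda v: v > 1) == (0.0, 0.0)

    def test_site_fraction_direct_count(self):
        coords = np.array([[0.0, 0], [50.0, 20.0], [20.0, 60.0]])
        vals = np.array([0.2, 0.4, 1.7])
        grid = make_grid(coords, ncells=10)
        surf = idw(coords, vals, grid)
        site_fr, _ = detect_polluted_area(vals, surf, lambda v: v > 1)
        assert site_fr == pytest.approx(100.0 / 3.0)

    def test_area_fraction_stable_across_resolutions(self, smooth_field):
        coords, vals = smooth_field
        vm = fit_variogram(coords, vals)
        thr = float(np.median(vals))
        fracs = []
        for ncells in (50, 100):
            grid = make_grid(coords, ncells=ncells)
            mask = study_mask(coords, grid)
            comb = combined_surface(
                ordinary_kriging(coords, vals, grid, vm, mask=mask),
                idw(coords, vals, grid, mask=mask))
            fracs.append(comb.area_fraction(lambda v: v > thr))
        assert abs(fracs[0] - fracs[1]) < 2.0

    def test_pollution_area_table_shape(self, survey30, refs):
        table, surfaces = pollution_area_table(survey30, refs)
        assert list(table["metal"]) == list(survey30.metals) + ["all"]
        assert ((table["site_pct"] >= 0) & (table["site_pct"] <= 100)).all()
        assert ((table["interp_pct"] >= 0) & (table["interp_pct"] <= 100)).all()
        # Table-1-calibrated survey: Pb is above background everywhere
        pb = table.set_index("metal").loc["Pb"]
        assert pb["site_pct"] == 100.0 and pb["interp_pct"] == 100.0


def test_ascii_grid_roundtrip(tmp_path, smooth_field):
    coords, vals = smooth_field
    grid = make_grid(coords, ncells=10)
    surf = idw(coords, vals, grid)
    path = tmp_path / "surface.asc"
    surf.write_ascii(path)
    lines = path.read_text().splitlines()
    assert lines[0] == f"ncols {grid.ncols}"
    body = np.loadtxt(lines[6:])
    assert body.shape == (grid.nrows, grid.ncols)
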