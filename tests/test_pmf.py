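import numpy as np
import pytest

from soilcap.core import default_references
from soilcap.pmf import (PMFSolution, build_uncertainty, contributions,
                         diagnostics, fit, fit_survey, match_factors)
from soilcap.synthetic import generate_pmf_dataset, generate_survey


@pytest.fixture(scope="module")
def planted():
    ds, truth = generate_pmf_dataset(n=30, m=8, p=3, noise_level=0.05,
                                     seed=2, mass_split=(0.2, 0.3, 0.5))
    return ds, truth


@pytest.fixture(scope="module")
def planted_fit(planted):
    ds, truth = planted
    X, um = build_uncertainty(ds)
    return fit(X, um.u, p=3, n_runs=10, seed=3, max_iter=4000,
               metals=ds.metals), truth


class TestBuildUncertainty:
    def test_below_mdl_branch(self):
        # Pb at 0.1 <= MDL 0.25: u = 5/6 * MDL, concentration -> MDL/2
        survey = generate_survey(seed=1)
        survey.samples[0].conc["Pb"] = 0.1
        X, um = build_uncertainty(survey)
        j = survey.metals.index("Pb")
        assert um.u[0, j] == pytest.approx(5.0 / 6.0 * 0.25)
        assert X[0, j] == pytest.approx(0.125)
        assert um.substituted[0, j]
        assert not um.substituted[1, j]

    def test_above_mdl_formula(self):
        refs = default_references({"Pb": {"error_fraction_sigma": 0.1}})
        survey = generate_survey(seed=1, references=refs)
        survey.samples[0].conc["Pb"] = 100.0
        X, um = build_uncertainty(survey, refs)
        j = survey.metals.index("Pb")
        # sqrt((0.1*100)^2 + (0.125)^2)
        assert um.u[0, j] == pytest.approx(np.sqrt(100.0 + 0.015625))

    def test_zero_sigma_limit(self):
        refs = default_references({m: {"error_fraction_sigma": 0.0}
                                   for m in default_references()})
        survey = generate_survey(seed=1, references=refs)
        X, um = build_uncertainty(survey, refs)
        for j, m in enumerate(survey.metals):
            above = ~um.substituted[:, j]
            np.testing.assert_allclose(um.u[above, j], 0.5 * refs[m].mdl)

    def test_uncertainties_strictly_positive(self, survey30):
        _, um = build_uncertainty(survey30)
        assert np.all(um.u > 0)


class TestFit:
    def test_q_monotone_non_increasing(self, planted_fit):
        sol, _ = planted_fit
        diffs = np.diff(sol.q_history)
        assert np.all(diffs <= 1e-8 * np.abs(sol.q_history[:-1]) + 1e-12)

    def test_noiseless_data_reaches_near_zero_q(self):
        ds, truth = generate_pmf_dataset(noise_level=0.0, seed=5)
        X = truth.X_true
        U = 0.1 * X + 0.01
        sol = fit(X, U, p=3, n_runs=5, seed=1, max_iter=8000, tol=1e-10)
        assert sol.Q < 1e-3
        np.testing.assert_allclose(sol.Xhat, X, rtol=1e-3)

    def test_rank_one_recovered_by_single_factor(self):
        rng = np.random.default_rng(6)
        X = np.outer(rng.uniform(1, 2, 20), rng.uniform(5, 50, 8))
        sol = fit(X, 0.1 * X + 0.01, p=1, n_runs=3, seed=2, max_iter=4000,
                  tol=1e-10)
        assert sol.Q < 1e-4
        fc, _ = contributions(sol)
        np.testing.assert_allclose(fc, [100.0])

    def test_profiles_recovered_up_to_permutation(self, planted_fit):
        sol, truth = planted_fit
        _, cos = match_factors(sol.F, truth.F_true)
        assert cos > 0.95

    def test_mass_split_recovered_within_five_points(self, planted_fit):
        sol, truth = planted_fit
        perm, _ = match_factors(sol.F, truth.F_true)
        fc, _ = contributions(sol)
        est = fc[perm]
        np.testing.assert_allclose(est, 100 * truth.mass_split, atol=5.0)

    def test_scale_convention_leaves_reconstruction_unchanged(self, planted_fit):
        sol, _ = planted_fit
        np.testing.assert_allclose(sol.G.mean(axis=0), 1.0, rtol=1e-9)
        # re-deriving Q from the normalized G, F must give the stored Q
        q = float((((sol.X - sol.G @ sol.F) / sol.U) ** 2).sum())
        assert q == pytest.approx(sol.Q, rel=1e-9)

    def test_seed_determinism_and_run_stability(self, planted):
        ds, _ = planted
        X, um = build_uncertainty(ds)
        a = fit(X, um.u, p=3, n_runs=4, seed=7, max_iter=2000)
        b = fit(X, um.u, p=3, n_runs=4, seed=7, max_iter=2000)
        np.testing.assert_array_equal(a.G, b.G)
        np.testing.assert_array_equal(a.F, b.F)
        c = fit(X, um.u, p=3, n_runs=4, seed=8, max_iter=2000)
        assert abs(c.Q - a.Q) / a.Q < 0.01  # well-posed: seeds agree on Q

    def test_rank_guard(self, planted):
        ds, _ = planted
        X, um = build_uncertainty(ds)
        with pytest.raises(ValueError):
            fit(X, um.u, p=8)


class TestContributions:
    def test_two_identical_factors_split_evenly(self):
        n, m = 10, 8
        G = np.ones((n, 2))
        F = np.tile(np.linspace(1, 8, m), (2, 1))
        sol = PMFSolution(G=G, F=F, Q=0.0, q_per_run=[0.0],
                          q_history=np.array([0.0]), converged=True,
                          metals=tuple(range(m)), X=G @ F,
                          U=np.ones((n, m)))
        fc, species = contributions(sol)
        np.testing.assert_allclose(fc, [50.0, 50.0])
        np.testing.assert_allclose(species.sum(axis=0), 100.0)

    def test_mean_normalized_basis(self, planted_fit):
        sol, _ = planted_fit
        fc, _ = contributions(sol, basis="mean_normalized")
        assert fc.sum() == pytest.approx(100.0)

    def test_species_shares_column_normalized(self, planted_fit):
        sol, _ = planted_fit
        _, species = contributions(sol)
        np.testing.assert_allclose(species.sum(axis=0), 100.0, rtol=1e-9)


class TestDiagnostics:
    def test_elbow_at_true_factor_count(self, planted):
        ds, _ = planted
        X, um = build_uncertainty(ds)
        sols = {p: fit(X, um.u, p=p, n_runs=4, seed=1, max_iter=3000)
                for p in (2, 3, 4)}
        diag = diagnostics(sols).set_index("p")
        ratio = diag["Q_over_Qexp"]
        assert ratio[3] < 0.5 * ratio[2]       # sharp drop at the true p
        assert ratio[4] > 0.2 * ratio[3]       # then flattens

    def test_exact_fit_diagnostics(self):
        ds, truth = generate_pmf_dataset(noise_level=0.0, seed=9)
        X = truth.X_true
        U = 0.1 * X + 0.01
        sols = {p: fit(X, U, p=p, n_runs=3, seed=1, max_iter=8000, tol=1e-12)
                for p in (3, 4)}
        diag = diagnostics(sols).set_index("p")
        assert diag.loc[3, "pct_residuals_outside_3"] == 0.0
        r2_cols = [c for c in diag.columns if c.startswith("r2_")
                   and c not in ("r2_min", "r2_median")]
        for c in r2_cols:
            assert diag.loc[3, c] == pytest.approx(1.0, abs=1e-4)

    def test_requires_multiple_candidates(self, planted_fit):
        sol, _ = planted_fit
        with pytest.raises(ValueError):
            diagnostics({3: sol})


def test_fit_survey_end_to_end(survey30):
    sol = fit_survey(survey30, p=3, n_runs=3, seed=4, max_iter=2000)
    assert sol.G.shape == (30, 3) and sol.F.shape == (3, 8)
    assert np.all(sol.G >= 0) and np.all(sol.F >= 0)
    assert set(sol.r2_per_metal) == set(survey30.metals)
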